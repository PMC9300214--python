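"""Gaussian trait-matching mate-preference model.

The model describes the joint distribution of a quantitative trait measured
in the two members of a mated pair.  Females carry trait ``X ~ N(mu_x,
sigma_x^2)`` and males ``Y ~ N(mu_y, sigma_y^2)``; a random encounter between
a female with trait ``x`` and a male with trait ``y`` results in mating with
probability

    P(mate | x, y) = gamma * exp(-alpha * (x - y - delta)**2)

where ``alpha >= 0`` is the strength of preference (units 1/trait^2),
``delta`` is the trait difference ``x - y`` that maximises the mating
probability (``delta = 0`` is strict trait matching), and ``gamma`` is the
mating probability at the optimum.  Conditioning on a successful mating gives
a pair density proportional to ``f(x) f(y) exp(-alpha (x-y-delta)^2)`` whose
normalising constant is available in closed form via the moment-generating
function of a noncentral chi-square variable; ``gamma`` cancels and is never
estimable from pair/single phenotypes alone.

Everything here is pure computation on validated parameter/data containers;
fitting lives in :mod:`matefit.inference` and data simulation in
:mod:`matefit.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "TraitData",
    "MultiPopData",
    "mating_probability",
    "pair_normalizer",
    "log_pair_normalizer",
    "conditional_pair_logdensity",
    "conditional_pair_moments",
    "log_likelihood",
    "multipop_log_likelihood",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelParams:
    """Parameter vector theta = (alpha, delta, mu_x, mu_y, sigma_x, sigma_y).

    ``gamma`` (the mating ceiling) is carried for simulation and for
    evaluating raw mating probabilities; the conditional pair density and the
    likelihood are invariant to it.

    Parameters
    ----------
    alpha
        Strength of mate preference, ``>= 0``, units 1/trait^2.
    delta
        Optimal offset ``x - y`` (female minus male trait), trait units.
    mu_x, mu_y
        Female and male population trait means, trait units.
    sigma_x, sigma_y
        Female and male population trait standard deviations, ``> 0``.
    gamma
        Maximum mating probability, in ``(0, 1]``.  Simulation-only.
    """

    alpha: float
    delta: float
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.alpha, self.delta, self.mu_x, self.mu_y,
                self.sigma_x, self.sigma_y, self.gamma)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all parameters must be finite")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError(
                "sigma_x and sigma_y must be > 0 (the model assumes "
                f"continuous trait variation); got {self.sigma_x}, {self.sigma_y}"
            )
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")

    def as_array(self) -> np.ndarray:
        """The estimable parameters as ``[alpha, delta, mu_x, mu_y, sigma_x, sigma_y]``."""
        return np.array([self.alpha, self.delta, self.mu_x, self.mu_y,
                         self.sigma_x, self.sigma_y])

    def scaled(self, c: float) -> "ModelParams":
        """Parameters after the unit change ``trait -> c * trait``.

        Means, SDs and delta scale by ``c``; alpha scales by ``1/c^2``;
        gamma is dimensionless.
        """
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return replace(self, alpha=self.alpha / c**2, delta=self.delta * c,
                       mu_x=self.mu_x * c, mu_y=self.mu_y * c,
                       sigma_x=self.sigma_x * c, sigma_y=self.sigma_y * c)


def _as_1d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).reshape(-1)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class TraitData:
    """Trait observations for one population.

    ``pairs_x[i]`` and ``pairs_y[i]`` are the female and male traits of the
    i-th mated pair; the pairing itself is the signal and the two arrays are
    never reordered independently.  ``singles_x`` / ``singles_y`` hold traits
    of females / males not observed in any pair.  Either singles array may be
    empty, at the cost of the identifiability of ``delta`` (see
    :func:`matefit.inference.fit_mle`).
    """

    pairs_x: np.ndarray
    pairs_y: np.ndarray
    singles_x: np.ndarray = field(default_factory=lambda: np.empty(0))
    singles_y: np.ndarray = field(default_factory=lambda: np.empty(0))
    units_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs_x", _as_1d(self.pairs_x, "pairs_x"))
        object.__setattr__(self, "pairs_y", _as_1d(self.pairs_y, "pairs_y"))
        object.__setattr__(self, "singles_x", _as_1d(self.singles_x, "singles_x"))
        object.__setattr__(self, "singles_y", _as_1d(self.singles_y, "singles_y"))
        if self.pairs_x.size != self.pairs_y.size:
            raise ValueError("pairs_x and pairs_y must have equal length")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[float, float]],
                   singles_x: Sequence[float] = (),
                   singles_y: Sequence[float] = (),
                   units_label: str = "") -> "TraitData":
        arr = np.asarray(list(pairs), dtype=float)
        if arr.size == 0:
            arr = arr.reshape(0, 2)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("pairs must be a sequence of (x, y) tuples")
        return cls(arr[:, 0], arr[:, 1], np.asarray(singles_x, dtype=float),
                   np.asarray(singles_y, dtype=float), units_label)

    @property
    def n_pairs(self) -> int:
        return self.pairs_x.size

    @property
    def n_singles_x(self) -> int:
        return self.singles_x.size

    @property
    def n_singles_y(self) -> int:
        return self.singles_y.size

    @property
    def n_total(self) -> int:
        return self.n_pairs + self.n_singles_x + self.n_singles_y

    def all_x(self) -> np.ndarray:
        """All female observations: paired plus single."""
        return np.concatenate([self.pairs_x, self.singles_x])

    def all_y(self) -> np.ndarray:
        """All male observations: paired plus single."""
        return np.concatenate([self.pairs_y, self.singles_y])

    def scaled(self, c: float) -> "TraitData":
        """All trait values multiplied by ``c`` (unit conversion)."""
        return TraitData(self.pairs_x * c, self.pairs_y * c,
                         self.singles_x * c, self.singles_y * c,
                         self.units_label)


@dataclass(frozen=True)
class MultiPopData:
    """Labelled per-population trait data for the shared-preference model."""

    populations: tuple[tuple[str, TraitData], ...]

    def __post_init__(self) -> None:
        pops = tuple(self.populations)
        object.__setattr__(self, "populations", pops)
        if len(pops) < 1:
            raise ValueError("at least one population is required")
        labels = [label for label, _ in pops]
        if len(set(labels)) != len(labels):
            raise ValueError(f"population labels must be unique, got {labels}")


def mating_probability(x, y, params: ModelParams):
    """Probability that an encounter between female ``x`` and male ``y`` mates.

    Evaluates ``gamma * exp(-alpha (x - y - delta)^2)``; vectorised over
    ``x`` and ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("trait values must be finite")
    out = params.gamma * np.exp(-params.alpha * (x - y - params.delta) ** 2)
    return out if out.ndim else float(out)


def log_pair_normalizer(params: ModelParams) -> float:
    """Log of E[exp(-alpha (X - Y - delta)^2)] under random encounter.

    With ``t = -alpha (sigma_x^2 + sigma_y^2)`` and noncentrality
    ``lam = (mu_x - mu_y - delta)^2 / (sigma_x^2 + sigma_y^2)``, the
    expectation is the MGF of a noncentral chi-square(1, lam) variable at t:
    ``exp(lam t / (1 - 2t)) / sqrt(1 - 2t)``.  Because ``t <= 0`` the
    expression is always defined; it is evaluated in log space so that large
    ``alpha`` cannot underflow.
    """
    s2 = params.sigma_x**2 + params.sigma_y**2
    t = -params.alpha * s2
    lam = (params.mu_x - params.mu_y - params.delta) ** 2 / s2
    # 1 - 2t = 1 + 2*alpha*s2 >= 1
    return lam * t / (1.0 - 2.0 * t) - 0.5 * math.log1p(-2.0 * t)


def pair_normalizer(params: ModelParams) -> float:
    """E[exp(-alpha (X - Y - delta)^2)]; in (0, 1], equal to 1 iff alpha = 0.

    This is the marginal mating probability divided by gamma, and the
    normalising constant of the conditional pair density.
    """
    return math.exp(log_pair_normalizer(params))


def _normal_logpdf(v: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    z = (v - mu) / sigma
    return -0.5 * _LOG_2PI - math.log(sigma) - 0.5 * z * z


def conditional_pair_logdensity(x, y, params: ModelParams):
    """Log density of the trait pair (x, y) given that the pair mated.

    log f(x) + log f(y) - alpha (x - y - delta)^2 - log normalizer.  The
    density integrates to one over the plane and does not depend on gamma.
    Only the log form is exposed: for large alpha the raw density underflows.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("trait values must be finite")
    out = (_normal_logpdf(x, params.mu_x, params.sigma_x)
           + _normal_logpdf(y, params.mu_y, params.sigma_y)
           - params.alpha * (x - y - params.delta) ** 2
           - log_pair_normalizer(params))
    return out if out.ndim else float(out)


def conditional_pair_moments(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Mean vector and covariance matrix of (X, Y) within mated pairs.

    Completing the square in the exponent of the conditional pair density
    shows it is bivariate normal with precision matrix

        P = [[1/sigma_x^2 + 2 alpha,        -2 alpha],
             [-2 alpha,         1/sigma_y^2 + 2 alpha]]

    and mean ``P^{-1} b`` where ``b = (mu_x/sigma_x^2 + 2 alpha delta,
    mu_y/sigma_y^2 - 2 alpha delta)``.  Used as an exact oracle for the
    simulator and for the correlation implied by (alpha, sigma_x, sigma_y).
    """
    a2 = 2.0 * params.alpha
    prec = np.array([[1.0 / params.sigma_x**2 + a2, -a2],
                     [-a2, 1.0 / params.sigma_y**2 + a2]])
    b = np.array([params.mu_x / params.sigma_x**2 + a2 * params.delta,
                  params.mu_y / params.sigma_y**2 - a2 * params.delta])
    cov = np.linalg.inv(prec)
    mean = cov @ b
    return mean, cov


def log_likelihood(params: ModelParams, data: TraitData) -> float:
    """Log likelihood of mated pairs plus unpaired singles.

    Pairs contribute the conditional pair log density; singles contribute
    their marginal normal log density.  Terms for empty singles sets are
    simply absent.  The value is invariant to ``gamma``.
    """
    if data.n_total == 0:
        raise ValueError("dataset is empty: need at least one pair or single")
    ll = 0.0
    if data.n_pairs:
        ll += float(np.sum(conditional_pair_logdensity(
            data.pairs_x, data.pairs_y, params)))
    if data.n_singles_x:
        ll += float(np.sum(_normal_logpdf(data.singles_x, params.mu_x,
                                          params.sigma_x)))
    if data.n_singles_y:
        ll += float(np.sum(_normal_logpdf(data.singles_y, params.mu_y,
                                          params.sigma_y)))
    return ll


def multipop_log_likelihood(
    alpha: float,
    delta: float,
    pop_nuisance: Sequence[tuple[float, float, float, float]],
    data: MultiPopData,
    gamma: float = 1.0,
) -> float:
    """Joint log likelihood of several populations sharing (alpha, delta).

    Each population keeps its own trait moments ``(mu_x, mu_y, sigma_x,
    sigma_y)`` while the preference parameters are common.  This is the
    structured-population extension for discrete subpopulations believed to
    share one preference rule.
    """
    if len(pop_nuisance) != len(data.populations):
        raise ValueError(
            f"got {len(pop_nuisance)} nuisance tuples for "
            f"{len(data.populations)} populations"
        )
    total = 0.0
    for (mu_x, mu_y, sigma_x, sigma_y), (_, pop) in zip(pop_nuisance,
                                                        data.populations):
        params = ModelParams(alpha, delta, mu_x, mu_y, sigma_x, sigma_y, gamma)
        total += log_likelihood(params, pop)
    return total
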