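"""Simulation of populations and mated pairs under the preference model.

Pairs are generated by rejection sampling of the mating process itself: a
female and a male candidate are drawn independently from their population
trait distributions and accepted as a mated pair with probability
``gamma * exp(-alpha (x - y - delta)^2)``.  Candidates are drawn fresh on
every attempt (no pool depletion), matching the independence assumptions
under which the conditional pair density was derived.  Singles are drawn
independently of the pairing process, as the model assumes unpaired samples
follow the marginal trait distributions.

Two stress-test designs are included: gamma-distributed (skewed) trait
variants, and "hidden" population structure where mating happens only within
three subpopulations whose means are shifted by ``-epsilon, 0, +epsilon``
before everything is pooled without labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model import ModelParams, TraitData

__all__ = [
    "SimulationConfig",
    "SimulationError",
    "SimulationStats",
    "simulate_singles",
    "simulate_pairs",
    "simulate_dataset",
    "simulate_structured",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationStats:
    """Bookkeeping from one rejection-sampling run."""

    n_attempted: int
    n_accepted: int

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_attempted if self.n_attempted else 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one simulated dataset.

    Parameters
    ----------
    params
        Population and mating-process parameters; ``gamma`` is the
        acceptance ceiling of the rejection sampler.
    n_pairs
        Number of mated pairs to accept.
    n_singles
        Total unpaired individuals, split exactly 50/50 by sex (must be
        even).
    trait_family
        ``"normal"`` or ``"gamma"``.  Gamma draws use shape ``gamma_shape``
        and scale ``gamma_scale`` and by default are shifted/scaled to hit
        the configured per-sex mean and SD, so skewness is the only model
        violation; ``standardize_gamma=False`` keeps the raw gamma scale.
    structure_epsilon
        0 for a homogeneous population; otherwise three equal subpopulations
        with per-sex means shifted by ``-epsilon, 0, +epsilon`` and mating
        confined within subpopulations (see :func:`simulate_structured`).
    seed
        Seed for :func:`numpy.random.default_rng`; identical seeds give
        identical datasets.
    max_attempts
        Cap on candidate draws per requested pair before the sampler gives
        up (guards against pathological alpha/mean combinations with a
        vanishing acceptance rate).
    """

    params: ModelParams
    n_pairs: int = 100
    n_singles: int = 100
    trait_family: str = "normal"
    gamma_shape: float = 2.0
    gamma_scale: float = 4.0
    standardize_gamma: bool = True
    structure_epsilon: float = 0.0
    seed: int | None = None
    max_attempts: int = 100_000

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if self.n_singles < 0 or self.n_singles % 2:
            raise ValueError("n_singles must be a non-negative even number")
        if self.trait_family not in ("normal", "gamma"):
            raise ValueError(f"unknown trait_family {self.trait_family!r}")
        if self.trait_family == "gamma" and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.structure_epsilon < 0:
            raise ValueError("structure_epsilon must be >= 0")


def _draw_traits(rng: np.random.Generator, n: int, mu: float, sigma: float,
                 config: SimulationConfig) -> np.ndarray:
    if config.trait_family == "normal":
        return rng.normal(mu, sigma, size=n)
    k, scale = config.gamma_shape, config.gamma_scale
    g = rng.gamma(k, scale, size=n)
    if config.standardize_gamma:
        # shift/scale to the target (mu, sigma); skewness 2/sqrt(k) survives
        return mu + sigma * (g - k * scale) / (scale * math.sqrt(k))
    return g


def simulate_singles(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> TraitData:
    """Draw the unpaired sample: n_singles/2 females and n_singles/2 males."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = config.params
    half = config.n_singles // 2
    sx = _draw_traits(rng, half, p.mu_x, p.sigma_x, config)
    sy = _draw_traits(rng, half, p.mu_y, p.sigma_y, config)
    return TraitData(np.empty(0), np.empty(0), sx, sy)


def simulate_pairs(config: SimulationConfig,
                   rng: np.random.Generator | None = None,
                   return_stats: bool = False):
    """Rejection-sample mated pairs from the mating process.

    Candidates ``(x, y)`` are drawn independently from the per-sex trait
    distributions and accepted with probability
    ``gamma * exp(-alpha (x - y - delta)^2)`` until ``n_pairs`` pairs have
    been accepted.  The long-run acceptance rate equals gamma times the
    marginal mating probability (the pair-density normaliser).

    With ``return_stats=True`` returns ``(TraitData, SimulationStats)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = config.params
    n = config.n_pairs
    acc_x: list[np.ndarray] = []
    acc_y: list[np.ndarray] = []
    n_accepted = 0
    n_attempted = 0
    budget = config.max_attempts * max(n, 1)
    batch = max(256, 4 * n)
    while n_accepted < n:
        if n_attempted >= budget:
            rate = n_accepted / n_attempted if n_attempted else 0.0
            raise SimulationError(
                f"rejection sampler exhausted {n_attempted} attempts for "
                f"{n} pairs (acceptance rate {rate:.2e}); check that alpha, "
                "delta and the trait means are compatible")
        m = min(batch, budget - n_attempted)
        x = _draw_traits(rng, m, p.mu_x, p.sigma_x, config)
        y = _draw_traits(rng, m, p.mu_y, p.sigma_y, config)
        prob = p.gamma * np.exp(-p.alpha * (x - y - p.delta) ** 2)
        keep = rng.random(m) < prob
        acc_x.append(x[keep])
        acc_y.append(y[keep])
        n_accepted += int(keep.sum())
        n_attempted += m
    if n == 0:
        out = TraitData(np.empty(0), np.empty(0))
    else:
        out = TraitData(np.concatenate(acc_x)[:n], np.concatenate(acc_y)[:n])
    if return_stats:
        return out, SimulationStats(n_attempted, n_accepted)
    return out


def simulate_dataset(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> TraitData:
    """Pairs plus singles from one configuration (one population study)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.structure_epsilon > 0:
        return simulate_structured(config, rng)
    pairs = simulate_pairs(config, rng)
    singles = simulate_singles(config, rng)
    return TraitData(pairs.pairs_x, pairs.pairs_y,
                     singles.singles_x, singles.singles_y)


def _split_counts(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def simulate_structured(config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> TraitData:
    """Pooled data from three hidden subpopulations.

    Per-sex means are shifted by ``-epsilon, 0, +epsilon`` in the three
    subpopulations; mating takes place only within each subpopulation.  All
    pairs and singles are pooled with no labels, mimicking structure the
    observer is unaware of.  ``epsilon = 0`` degenerates to the homogeneous
    process.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    eps = config.structure_epsilon
    p = config.params
    pair_counts = _split_counts(config.n_pairs, 3)
    # keep per-subpopulation singles counts even (males = females)
    single_counts = [2 * c for c in _split_counts(config.n_singles // 2, 3)]
    px, py, sx, sy = [], [], [], []
    for shift, np_k, ns_k in zip((-eps, 0.0, eps), pair_counts, single_counts):
        sub_params = replace(p, mu_x=p.mu_x + shift, mu_y=p.mu_y + shift)
        sub = replace(config, params=sub_params, n_pairs=np_k, n_singles=ns_k,
                      structure_epsilon=0.0)
        pairs = simulate_pairs(sub, rng)
        singles = simulate_singles(sub, rng)
        px.append(pairs.pairs_x); py.append(pairs.pairs_y)
        sx.append(singles.singles_x); sy.append(singles.singles_y)
    return TraitData(np.concatenate(px), np.concatenate(py),
                     np.concatenate(sx), np.concatenate(sy))
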