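"""Interpretation utilities for fitted preference parameters.

Three tools translate (alpha, delta) into quantities a field biologist can
reason about: the p% preference interval (the range of trait differences
within p% of the maximum mating probability), the within-pair trait
correlation implied by the model, and joint pair-density surfaces comparing
assortative with random mating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .model import (ModelParams, conditional_pair_logdensity,
                    conditional_pair_moments)

__all__ = [
    "PreferenceInterval",
    "preference_interval",
    "correlation_from_params",
    "joint_density_surface",
    "plot_joint_density",
]


@dataclass(frozen=True)
class PreferenceInterval:
    """Trait-difference interval delta +/- sqrt(-log(1 - p/100) / alpha).

    For trait differences ``x - y`` inside the interval, the mating
    probability is within p% of its maximum gamma; at either endpoint it
    equals ``(1 - p/100) * gamma`` exactly.  Stronger preference (larger
    alpha) narrows the interval; delta centres it.
    """

    p: float
    lower: float
    upper: float
    center: float

    @property
    def width(self) -> float:
        return self.upper - self.lower


def preference_interval(alpha: float, delta: float,
                        p: float = 10.0) -> PreferenceInterval:
    """Interval of trait differences within p% of the maximum mating probability.

    Parameters
    ----------
    alpha
        Preference strength, must be > 0 (at alpha = 0 every trait
        difference mates with the same probability and the interval is
        infinite).
    delta
        Optimal offset; the interval's centre.
    p
        Percent reduction threshold, in (0, 100).  Defaults to 10, i.e. the
        range of differences mating at >= 90% of the ceiling.
    """
    if not 0.0 < p < 100.0:
        raise ValueError(f"p must be in (0, 100), got {p}")
    if alpha <= 0:
        raise ValueError(
            "preference interval is infinite at alpha = 0 (random mating "
            "with respect to the trait); alpha must be > 0")
    half = math.sqrt(-math.log1p(-p / 100.0) / alpha)
    return PreferenceInterval(p=p, lower=delta - half, upper=delta + half,
                              center=delta)


def correlation_from_params(alpha: float, sigma_x: float, sigma_y: float,
                            method: str = "closed_form") -> float:
    """Within-pair trait correlation implied by (alpha, sigma_x, sigma_y).

    The conditional pair density is bivariate normal with precision matrix
    ``[[1/sigma_x^2 + 2a, -2a], [-2a, 1/sigma_y^2 + 2a]]`` (a = alpha), so

        rho = 2 alpha / sqrt((1/sigma_x^2 + 2 alpha)(1/sigma_y^2 + 2 alpha))

    which is 0 iff alpha = 0, strictly increasing in alpha, increasing in
    either SD at fixed alpha, and approaches 1 as alpha -> infinity.  This
    is why a sample correlation alone cannot measure preference strength:
    the same alpha yields different correlations at different trait
    variances.  ``method="quadrature"`` integrates the pair density
    numerically instead, as an independent cross-check of the closed form.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if sigma_x <= 0 or sigma_y <= 0:
        raise ValueError("standard deviations must be > 0")
    if method == "closed_form":
        a2 = 2.0 * alpha
        return a2 / math.sqrt((1.0 / sigma_x**2 + a2) * (1.0 / sigma_y**2 + a2))
    if method == "quadrature":
        return _correlation_by_quadrature(alpha, sigma_x, sigma_y)
    raise ValueError(f"unknown method {method!r}")


def _correlation_by_quadrature(alpha: float, sigma_x: float,
                               sigma_y: float) -> float:
    # correlation is invariant to the means and delta; centre everything
    params = ModelParams(alpha, 0.0, 0.0, 0.0, sigma_x, sigma_y)
    lim_x = 8.5 * sigma_x
    lim_y = 8.5 * sigma_y

    def moment(fn):
        val, _ = integrate.dblquad(
            lambda y, x: fn(x, y) * math.exp(
                conditional_pair_logdensity(x, y, params)),
            -lim_x, lim_x, lambda x: -lim_y, lambda x: lim_y,
            epsabs=1e-11, epsrel=1e-11)
        return val

    mx = moment(lambda x, y: x)
    my = moment(lambda x, y: y)
    vx = moment(lambda x, y: (x - mx) ** 2)
    vy = moment(lambda x, y: (y - my) ** 2)
    cxy = moment(lambda x, y: (x - mx) * (y - my))
    return cxy / math.sqrt(vx * vy)


def joint_density_surface(params: ModelParams, x_grid, y_grid
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Pair-density surfaces under the fitted model and under random mating.

    Returns ``(fitted, random)`` arrays of shape ``(len(x_grid),
    len(y_grid))`` with ``fitted[i, j]`` the conditional pair density at
    ``(x_grid[i], y_grid[j])`` and ``random`` the same surface with
    alpha = delta = 0 (the product of the marginal normals).  On a grid wide
    enough to hold the mass, ``surface.sum() * cell_area`` is ~1 for both.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    y_grid = np.asarray(y_grid, dtype=float)
    xx, yy = np.meshgrid(x_grid, y_grid, indexing="ij")
    fitted = np.exp(conditional_pair_logdensity(xx, yy, params))
    null_params = ModelParams(0.0, 0.0, params.mu_x, params.mu_y,
                              params.sigma_x, params.sigma_y, params.gamma)
    null = np.exp(conditional_pair_logdensity(xx, yy, null_params))
    return fitted, null


def plot_joint_density(params: ModelParams, data=None, n_grid: int = 201,
                       n_sigma: float = 4.0, path: str | None = None):
    """Contour plot of the fitted vs random-mating pair density.

    Thin convenience wrapper around matplotlib; returns the figure.  If
    ``data`` (a TraitData) is given its pairs are overplotted.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean, cov = conditional_pair_moments(params)
    sx, sy = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    x = np.linspace(mean[0] - n_sigma * sx, mean[0] + n_sigma * sx, n_grid)
    y = np.linspace(mean[1] - n_sigma * sy, mean[1] + n_sigma * sy, n_grid)
    fitted, null = joint_density_surface(params, x, y)
    fig, ax = plt.subplots()
    ax.contour(x, y, null.T, colors="grey", linewidths=0.8)
    cs = ax.contour(x, y, fitted.T, cmap="viridis")
    if data is not None and data.n_pairs:
        ax.scatter(data.pairs_x, data.pairs_y, s=8, c="k", alpha=0.5)
    ax.set_xlabel("female trait (x)")
    ax.set_ylabel("male trait (y)")
    fig.colorbar(cs, ax=ax, label="pair density")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig
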