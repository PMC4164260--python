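"""Dirichlet-process mixture core: CRP prior, conjugate Gaussian components.

The generative model clusters scalar intensities x_i under a Dirichlet
process prior DP(alpha * G0).  Integrating out the random measure gives
the Chinese-restaurant-process conditional: a new point joins an existing
cluster k with probability n_k / (n + alpha) and opens a new cluster with
probability alpha / (n + alpha).

The component likelihood F is a univariate Gaussian with unknown mean and
variance; G0 is the conjugate normal-inverse-gamma measure
NIG(mu0, kappa0, a0, b0).  With the component parameters integrated out,
the posterior predictive of a cluster given its sufficient statistics
(n, sum, sumsq) is a Student-t:

    nu = 2 a_n,   loc = mu_n,   scale^2 = b_n (kappa_n + 1) / (a_n kappa_n)

with the standard conjugate updates kappa_n = kappa0 + n,
mu_n = (kappa0 mu0 + sum) / kappa_n, a_n = a0 + n/2,
b_n = b0 + (sumsq + kappa0 mu0^2 - kappa_n mu_n^2) / 2.  The n = 0 case
is the prior predictive of the "zero component" that creates new classes.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "BaseMeasure",
    "ComponentStats",
    "ConcentrationParam",
    "crp_weights",
    "add_point",
    "remove_point",
    "predictive_logdensity",
    "expected_cluster_count",
]


@dataclasses.dataclass(frozen=True)
class BaseMeasure:
    """Normal-inverse-gamma base measure over (mean, variance).

    mu0 : prior mean; kappa0 : prior strength of the mean (pseudo-counts);
    a0, b0 : inverse-gamma shape and scale of the variance.
    """

    mu0: float
    kappa0: float = 0.01
    a0: float = 2.0
    b0: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa0 <= 0 or self.a0 <= 0 or self.b0 <= 0:
            raise ValueError("kappa0, a0, b0 must all be positive")

    @classmethod
    def from_data(cls, values: np.ndarray, kappa0: float = 0.01,
                  a0: float = 2.0) -> "BaseMeasure":
        """Empirical defaults: mu0 = data mean, b0 = data variance."""
        values = np.asarray(values, dtype=float)
        var = float(np.var(values))
        return cls(mu0=float(np.mean(values)), kappa0=kappa0, a0=a0,
                   b0=var if var > 0 else 1.0)


@dataclasses.dataclass(frozen=True)
class ComponentStats:
    """Sufficient statistics (count, sum, sum of squares) of one cluster."""

    n: int = 0
    sum: float = 0.0
    sumsq: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if self.n == 0 and (self.sum != 0.0 or self.sumsq != 0.0):
            raise ValueError("empty component must have zero sums")

    @classmethod
    def from_values(cls, values) -> "ComponentStats":
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            return cls()
        return cls(n=int(values.size), sum=float(values.sum()),
                   sumsq=float((values ** 2).sum()))


@dataclasses.dataclass(frozen=True)
class ConcentrationParam:
    """DP concentration alpha > 0; larger alpha favors more clusters."""

    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def add_point(stats: ComponentStats, x: float) -> ComponentStats:
    """Return stats with one observation x added."""
    x = float(x)
    return ComponentStats(n=stats.n + 1, sum=stats.sum + x,
                          sumsq=stats.sumsq + x * x)


def remove_point(stats: ComponentStats, x: float) -> ComponentStats:
    """Return stats with one previously added observation x removed."""
    if stats.n < 1:
        raise ValueError("cannot remove a point from an empty component")
    x = float(x)
    if stats.n == 1:
        return ComponentStats()
    return ComponentStats(n=stats.n - 1, sum=stats.sum - x,
                          sumsq=stats.sumsq - x * x)


def crp_weights(cluster_sizes, alpha) -> np.ndarray:
    """Chinese-restaurant-process conditional over K existing + 1 new cluster.

    Entry k < K is n_k / (n + alpha); the final entry alpha / (n + alpha)
    is the mass of a brand-new cluster.  Sums to 1.
    """
    a = alpha.alpha if isinstance(alpha, ConcentrationParam) else float(alpha)
    if a <= 0:
        raise ValueError("alpha must be positive")
    sizes = np.asarray(list(cluster_sizes), dtype=float)
    if sizes.size and sizes.min() < 1:
        raise ValueError("cluster sizes must be >= 1")
    n = sizes.sum()
    return np.concatenate([sizes, [a]]) / (n + a)


def _posterior_params(stats: ComponentStats, base: BaseMeasure):
    """Conjugate NIG posterior parameters (mu_n, kappa_n, a_n, b_n)."""
    n = stats.n
    kappa_n = base.kappa0 + n
    mu_n = (base.kappa0 * base.mu0 + stats.sum) / kappa_n
    a_n = base.a0 + 0.5 * n
    b_n = base.b0 + 0.5 * (stats.sumsq + base.kappa0 * base.mu0 ** 2
                           - kappa_n * mu_n ** 2)
    # guard against negative values from floating-point cancellation
    b_n = max(b_n, 1e-300)
    return mu_n, kappa_n, a_n, b_n


def predictive_logdensity(x: float, stats: ComponentStats,
                          base: BaseMeasure) -> float:
    """Log posterior-predictive density of x under one component.

    A Student-t in closed form; with ``stats.n == 0`` this is the prior
    predictive used for the cluster-creating zero component.
    """
    mu_n, kappa_n, a_n, b_n = _posterior_params(stats, base)
    nu = 2.0 * a_n
    scale2 = b_n * (kappa_n + 1.0) / (a_n * kappa_n)
    z2 = (float(x) - mu_n) ** 2 / (nu * scale2)
    return (math.lgamma(0.5 * (nu + 1.0)) - math.lgamma(0.5 * nu)
            - 0.5 * math.log(nu * math.pi * scale2)
            - 0.5 * (nu + 1.0) * math.log1p(z2))


def expected_cluster_count(n: int, alpha: float) -> float:
    """Expected number of CRP clusters after n points: sum alpha/(alpha+i-1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(1, n + 1, dtype=float)
    return float(np.sum(alpha / (alpha + i - 1.0)))
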