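"""Collapsed Gibbs sampling of DP-mixture labels with an MRF smoothness prior.

Each pixel i carries a cluster indicator S_i.  The full conditional of a
site combines three factors:

* the CRP prior: existing cluster k attracts mass n_k / (n - 1 + alpha),
  a new cluster attracts alpha / (n - 1 + alpha);
* the MRF smoothness factor exp(-H) with the binary (Potts-style) cost
  H(k) = -lambda * sum_{l in neighbors(i)} w_il * delta(k, S_l), so a
  candidate label matching many neighbors is boosted by exp(lambda) per
  matching neighbor, and a label matching none (in particular a brand-new
  label) has factor exactly 1;
* the collapsed Gaussian predictive of the pixel intensity under the
  cluster's current sufficient statistics (Student-t; see ``dp_core``).

A sweep visits every unmasked site in raster order, detaches the site
from its component, samples a new label from the conditional, and
re-attaches.  Empty components are removed and the labels compacted at
the end of each sweep.  The chain is considered converged once the number
of changed assignments per sweep stays below 1% of the number of sites
for ``window`` consecutive sweeps; by default the sampler caps at 200
sweeps.

With lambda = 0 the MRF factor is identically 1 and the sampler reduces
exactly to the plain (unconstrained) DP-mixture collapsed Gibbs sampler.
"""

from __future__ import annotations

import dataclasses

import numpy as np

import math

from scipy.special import gammaln

from .dp_core import BaseMeasure, ComponentStats, ConcentrationParam
from .image_io import IntensityImage, LabelField, compact_labels

__all__ = [
    "NeighborhoodGraph",
    "SmoothnessParam",
    "SamplerConfig",
    "SamplerState",
    "SamplerTrace",
    "binary_cost",
    "quadratic_cost",
    "site_conditional",
    "gibbs_sweep",
    "has_converged",
    "run_sampler",
    "DPMRFSegmenter",
]


@dataclasses.dataclass(frozen=True)
class SmoothnessParam:
    """MRF constraint strength lambda >= 0; 0 is the unconstrained case."""

    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


class NeighborhoodGraph:
    """Undirected pixel-adjacency graph on a 2-D grid.

    Sites are flat row-major indices into the grid.  Adjacency is stored
    as a padded (n_sites, max_degree) index array with -1 padding plus a
    parallel weight array.  Masked-out sites have no edges.
    """

    def __init__(self, shape: tuple[int, int], nbr_idx: np.ndarray,
                 nbr_wt: np.ndarray):
        self.shape = shape
        self.nbr_idx = nbr_idx
        self.nbr_wt = nbr_wt

    @classmethod
    def from_grid(cls, shape: tuple[int, int], mask: np.ndarray | None = None,
                  connectivity: int = 4, weight: float = 1.0
                  ) -> "NeighborhoodGraph":
        if connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        rows, cols = shape
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if connectivity == 8:
            offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        n = rows * cols
        deg = len(offsets)
        nbr_idx = np.full((n, deg), -1, dtype=np.int64)
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        for j, (dr, dc) in enumerate(offsets):
            r2, c2 = rr + dr, cc + dc
            ok = (r2 >= 0) & (r2 < rows) & (c2 >= 0) & (c2 < cols)
            ok &= mask & np.where(ok, mask[r2.clip(0, rows - 1), c2.clip(0, cols - 1)], False)
            flat = (r2 * cols + c2).ravel()
            col = nbr_idx[:, j]
            col[ok.ravel()] = flat[ok.ravel()]
        nbr_wt = np.where(nbr_idx >= 0, weight, 0.0)
        return cls((rows, cols), nbr_idx, nbr_wt)

    def neighbors(self, site: int) -> np.ndarray:
        """Flat indices of the neighbors of a flat site index."""
        row = self.nbr_idx[site]
        return row[row >= 0]

    def site_index(self, site) -> int:
        """Convert a (row, col) pair (or flat index) to a flat index."""
        if np.ndim(site) == 1 and len(site) == 2:
            r, c = int(site[0]), int(site[1])
            rows, cols = self.shape
            if not (0 <= r < rows and 0 <= c < cols):
                raise IndexError(f"site {site} outside grid {self.shape}")
            return r * cols + c
        return int(site)


def binary_cost(labels, site, candidate: int, lam,
                graph: NeighborhoodGraph) -> float:
    """Potts-style label cost H = -lambda * sum_l w_il * delta(candidate, S_l).

    Always <= 0; equals 0 when the candidate matches no neighbor (so the
    MRF factor exp(-H) is 1) and decreases by lambda * w per matching
    neighbor.
    """
    lam_v = lam.lam if isinstance(lam, SmoothnessParam) else float(lam)
    arr = labels.labels if isinstance(labels, LabelField) else np.asarray(labels)
    flat = arr.ravel()
    i = graph.site_index(site)
    row = graph.nbr_idx[i]
    ok = row >= 0
    match = ok & (flat[row.clip(min=0)] == candidate)
    return float(-lam_v * graph.nbr_wt[i][match].sum())


def quadratic_cost(theta_values, site, candidate_theta: float,
                   graph: NeighborhoodGraph) -> float:
    """Pairwise-difference cost sum_l ||candidate_theta - theta_l||^2.

    The continuous-parameter alternative to :func:`binary_cost`; provided
    for completeness, not used by the default pipeline.
    """
    theta = np.asarray(theta_values, dtype=float).ravel()
    i = graph.site_index(site)
    nbrs = graph.neighbors(i)
    return float(np.sum((candidate_theta - theta[nbrs]) ** 2))


@dataclasses.dataclass
class SamplerState:
    """Mutable state of the collapsed Gibbs chain.

    ``labels`` is flat (−1 = masked); component sufficient statistics are
    kept incrementally and must always equal a from-scratch recomputation
    from ``labels`` + ``data``.
    """

    labels: np.ndarray            # flat int64, -1 for masked-out sites
    data: np.ndarray              # flat float64 intensities
    comp_n: np.ndarray            # int64 per-cluster counts
    comp_sum: np.ndarray
    comp_sumsq: np.ndarray
    alpha: float
    lam: float
    base: BaseMeasure
    graph: NeighborhoodGraph

    @classmethod
    def from_image(cls, image: IntensityImage, alpha=1.0, lam=1.0,
                   base: BaseMeasure | None = None,
                   connectivity: int = 4, init: str = "per_site"
                   ) -> "SamplerState":
        """Initial state for the chain.

        ``per_site`` (default) starts every unmasked site in its own
        cluster; clusters then form by merging, which mixes well because
        absorbing a point into a fitting cluster is always likely under
        the collapsed conditional.  ``single`` starts all sites in one
        cluster; note that under the MRF factor a brand-new label at a
        site whose neighbors agree is suppressed by exp(-lambda *
        n_neighbors), so nucleation out of a single cluster is extremely
        slow — this init is provided for study, not for production use.
        """
        alpha = alpha.alpha if isinstance(alpha, ConcentrationParam) else float(alpha)
        lam = lam.lam if isinstance(lam, SmoothnessParam) else float(lam)
        if init not in ("per_site", "single"):
            raise ValueError("init must be 'per_site' or 'single'")
        valid = image.valid_mask().ravel()
        data = image.pixels.ravel().astype(np.float64)
        if base is None:
            base = BaseMeasure.from_data(data[valid])
        labels = np.full(valid.shape, -1, dtype=np.int64)
        if init == "per_site":
            labels[valid] = np.arange(int(valid.sum()))
        else:
            labels[valid] = 0
        graph = NeighborhoodGraph.from_grid(image.shape, image.mask, connectivity)
        state = cls(labels=labels, data=data,
                    comp_n=np.zeros(1, dtype=np.int64),
                    comp_sum=np.zeros(1), comp_sumsq=np.zeros(1),
                    alpha=alpha, lam=lam, base=base, graph=graph)
        state.recompute_stats()
        return state

    @property
    def n_clusters(self) -> int:
        return len(self.comp_n)

    @property
    def n_sites(self) -> int:
        return int(np.count_nonzero(self.labels >= 0))

    def components(self) -> list[ComponentStats]:
        return [ComponentStats(n=int(n), sum=float(s), sumsq=float(q))
                for n, s, q in zip(self.comp_n, self.comp_sum, self.comp_sumsq)]

    def recompute_stats(self) -> None:
        """Rebuild the sufficient statistics (and caches) from labels + data."""
        k = int(self.labels.max()) + 1 if np.any(self.labels >= 0) else 0
        valid = self.labels >= 0
        lab = self.labels[valid]
        x = self.data[valid]
        self.comp_n = np.bincount(lab, minlength=k).astype(np.int64)
        self.comp_sum = np.bincount(lab, weights=x, minlength=k)
        self.comp_sumsq = np.bincount(lab, weights=x * x, minlength=k)
        self._rebuild_cache()

    # -- cached Student-t predictive parameters ------------------------------
    # The collapsed conditional needs, for every component, the posterior
    # predictive evaluated at the site's intensity.  All x-independent parts
    # (log count, t location/shape, normalising constant) are cached per
    # component and refreshed incrementally on attach/detach, so the per-site
    # cost is a handful of vectorised operations over K clusters.

    @staticmethod
    def _t_params(n, total, totalsq, base: BaseMeasure):
        """(mu_n, const, coef, inv) of the posterior-predictive Student-t.

        logpdf(x) = const - coef * log1p((x - mu_n)^2 * inv).
        Works elementwise for array arguments.
        """
        kappa_n = base.kappa0 + n
        mu_n = (base.kappa0 * base.mu0 + total) / kappa_n
        a_n = base.a0 + 0.5 * n
        b_n = base.b0 + 0.5 * (totalsq + base.kappa0 * base.mu0 ** 2
                               - kappa_n * mu_n ** 2)
        b_n = np.maximum(b_n, 1e-300)
        nu = 2.0 * a_n
        scale2 = b_n * (kappa_n + 1.0) / (a_n * kappa_n)
        const = (gammaln(0.5 * (nu + 1.0)) - gammaln(0.5 * nu)
                 - 0.5 * np.log(nu * np.pi * scale2))
        return mu_n, const, 0.5 * (nu + 1.0), 1.0 / (nu * scale2)

    def _rebuild_cache(self) -> None:
        self.prior_mu, self.prior_const, self.prior_coef, self.prior_inv = (
            float(v) for v in self._t_params(0.0, 0.0, 0.0, self.base))
        n = self.comp_n.astype(np.float64)
        self.pred_mu, self.pred_const, self.pred_coef, self.pred_inv = \
            self._t_params(n, self.comp_sum, self.comp_sumsq, self.base)
        with np.errstate(divide="ignore"):
            self.log_n = np.where(self.comp_n > 0, np.log(n), -np.inf)

    def _refresh_component(self, k: int) -> None:
        n = int(self.comp_n[k])
        if n == 0:
            # log_n = -inf makes the CRP weight vanish; keep finite t params
            self.log_n[k] = -np.inf
            self.pred_mu[k] = self.prior_mu
            self.pred_const[k] = self.prior_const
            self.pred_coef[k] = self.prior_coef
            self.pred_inv[k] = self.prior_inv
            return
        # scalar twin of _t_params in pure math (hot path of the sweep)
        base = self.base
        kappa_n = base.kappa0 + n
        mu_n = (base.kappa0 * base.mu0 + float(self.comp_sum[k])) / kappa_n
        a_n = base.a0 + 0.5 * n
        b_n = base.b0 + 0.5 * (float(self.comp_sumsq[k])
                               + base.kappa0 * base.mu0 ** 2
                               - kappa_n * mu_n ** 2)
        if b_n < 1e-300:
            b_n = 1e-300
        nu = 2.0 * a_n
        scale2 = b_n * (kappa_n + 1.0) / (a_n * kappa_n)
        self.pred_mu[k] = mu_n
        self.pred_const[k] = (math.lgamma(0.5 * (nu + 1.0))
                              - math.lgamma(0.5 * nu)
                              - 0.5 * math.log(nu * math.pi * scale2))
        self.pred_coef[k] = 0.5 * (nu + 1.0)
        self.pred_inv[k] = 1.0 / (nu * scale2)
        self.log_n[k] = math.log(n)

    def check_consistency(self, atol: float = 1e-6) -> None:
        """Raise if incremental stats drifted from a from-scratch recompute."""
        saved = (self.comp_n.copy(), self.comp_sum.copy(), self.comp_sumsq.copy())
        self.recompute_stats()
        if (len(saved[0]) != len(self.comp_n)
                or not np.array_equal(saved[0], self.comp_n)
                or not np.allclose(saved[1], self.comp_sum, atol=atol)
                or not np.allclose(saved[2], self.comp_sumsq, atol=atol)):
            raise RuntimeError("sampler state inconsistent: stats != labels")

    def label_field(self) -> LabelField:
        return LabelField(labels=self.labels.reshape(self.graph.shape))


@dataclasses.dataclass
class SamplerTrace:
    """Per-sweep record of cluster count and changed assignments."""

    iterations: list = dataclasses.field(default_factory=list)
    n_clusters: list = dataclasses.field(default_factory=list)
    n_changed: list = dataclasses.field(default_factory=list)

    def append(self, iteration: int, n_clusters: int, n_changed: int) -> None:
        self.iterations.append(int(iteration))
        self.n_clusters.append(int(n_clusters))
        self.n_changed.append(int(n_changed))

    def __len__(self) -> int:
        return len(self.iterations)

    def to_table(self) -> str:
        lines = ["iteration\tn_clusters\tn_changed"]
        for it, k, ch in zip(self.iterations, self.n_clusters, self.n_changed):
            lines.append(f"{it}\t{k}\t{ch}")
        return "\n".join(lines) + "\n"


def _site_log_masses(state: SamplerState, site: int) -> np.ndarray:
    """Unnormalised log conditional over K existing clusters + 1 new.

    Assumes the site has already been detached from its component.  The
    common CRP denominator (n - 1 + alpha) is omitted (it cancels under
    normalisation).  Empty components carry -inf (zero CRP mass).
    """
    x = state.data[site]
    K = state.n_clusters
    logw = np.empty(K + 1)
    d = x - state.pred_mu
    logw[:K] = (state.log_n + state.pred_const
                - state.pred_coef * np.log1p(d * d * state.pred_inv))
    # MRF boost: +lambda per (weighted) neighbor sharing the candidate label
    if state.lam != 0.0:
        row = state.graph.nbr_idx[site]
        wts = state.graph.nbr_wt[site]
        for j in range(row.shape[0]):
            l = row[j]
            if l >= 0:
                sl = state.labels[l]
                if sl >= 0:
                    logw[sl] += state.lam * wts[j]
    dp = x - state.prior_mu
    logw[K] = (math.log(state.alpha) + state.prior_const
               - state.prior_coef * math.log1p(dp * dp * state.prior_inv))
    return logw


def site_conditional(state: SamplerState, site) -> np.ndarray:
    """Normalised full-conditional label distribution of one site.

    Precondition (standard collapsed-Gibbs bookkeeping): the site's
    current assignment has already been removed from its component, i.e.
    ``state.labels[site] == -1`` while the point is being resampled.
    Entry k < K is the probability of joining existing cluster k; the
    last entry is the probability of opening a new cluster.
    """
    i = state.graph.site_index(site)
    if state.labels[i] >= 0:
        raise RuntimeError(
            "site_conditional requires the site to be detached from its "
            "component first (collapsed-Gibbs bookkeeping)")
    logw = _site_log_masses(state, i)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def _detach(state: SamplerState, site: int) -> int:
    """Remove a site's point from its component; returns the old label."""
    k = int(state.labels[site])
    x = state.data[site]
    state.comp_n[k] -= 1
    if state.comp_n[k] == 0:
        state.comp_sum[k] = 0.0
        state.comp_sumsq[k] = 0.0
    else:
        state.comp_sum[k] -= x
        state.comp_sumsq[k] -= x * x
    state._refresh_component(k)
    state.labels[site] = -1
    return k


def _attach(state: SamplerState, site: int, k: int) -> None:
    """Assign a site to cluster k (k == K opens a new cluster)."""
    x = state.data[site]
    if k == state.n_clusters:
        state.comp_n = np.append(state.comp_n, 0)
        state.comp_sum = np.append(state.comp_sum, 0.0)
        state.comp_sumsq = np.append(state.comp_sumsq, 0.0)
        state.log_n = np.append(state.log_n, -np.inf)
        state.pred_mu = np.append(state.pred_mu, state.prior_mu)
        state.pred_const = np.append(state.pred_const, state.prior_const)
        state.pred_coef = np.append(state.pred_coef, state.prior_coef)
        state.pred_inv = np.append(state.pred_inv, state.prior_inv)
    state.comp_n[k] += 1
    state.comp_sum[k] += x
    state.comp_sumsq[k] += x * x
    state._refresh_component(k)
    state.labels[site] = k


def _compact_state(state: SamplerState) -> None:
    """Drop empty components and relabel to contiguous 0..K-1."""
    occupied = state.comp_n > 0
    if occupied.all():
        return
    new_of_old = np.full(state.n_clusters + 1, -1, dtype=np.int64)
    new_of_old[:-1][occupied] = np.arange(int(occupied.sum()))
    valid = state.labels >= 0
    state.labels[valid] = new_of_old[state.labels[valid]]
    state.comp_n = state.comp_n[occupied]
    state.comp_sum = state.comp_sum[occupied]
    state.comp_sumsq = state.comp_sumsq[occupied]
    state.log_n = state.log_n[occupied]
    state.pred_mu = state.pred_mu[occupied]
    state.pred_const = state.pred_const[occupied]
    state.pred_coef = state.pred_coef[occupied]
    state.pred_inv = state.pred_inv[occupied]


def gibbs_sweep(state: SamplerState, rng: np.random.Generator,
                order: np.ndarray | None = None) -> tuple[SamplerState, int]:
    """One Gibbs sweep over all unmasked sites in raster (or given) order.

    Mutates ``state`` in place and also returns it, together with the
    number of sites whose label changed.  Empty components are deleted
    and labels compacted at the end of the sweep.
    """
    if order is None:
        order = np.flatnonzero(state.labels >= 0)
    uniforms = rng.random(order.shape[0]).tolist()
    n_changed = 0
    for t, site in enumerate(order.tolist()):
        k_old = _detach(state, site)
        logw = _site_log_masses(state, site)
        K1 = logw.shape[0]
        if K1 <= 64:  # small-K fast path: plain Python beats numpy overhead
            lw = logw.tolist()
            m = max(lw)
            total = 0.0
            cum = lw  # reuse list for the running sums
            for j in range(K1):
                total += math.exp(lw[j] - m)
                cum[j] = total
            u = uniforms[t] * total
            k_new = K1 - 1
            for j in range(K1):
                if u < cum[j]:
                    k_new = j
                    break
        else:
            logw -= logw.max()
            w = np.exp(logw)
            np.cumsum(w, out=w)
            k_new = int(np.searchsorted(w, uniforms[t] * w[-1], side="right"))
            k_new = min(k_new, K1 - 1)  # guard against edge rounding
        _attach(state, site, k_new)
        if k_new != k_old:
            n_changed += 1
    _compact_state(state)
    return state, n_changed


def has_converged(trace: SamplerTrace, n_sites: int, window: int = 3) -> bool:
    """Burn-in rule: changed assignments stayed below 1% of the sites for
    the last ``window`` consecutive sweeps."""
    if window < 1:
        raise ValueError("window must be >= 1")
    changed = trace.n_changed if isinstance(trace, SamplerTrace) else list(trace)
    if len(changed) < window:
        return False
    thresh = 0.01 * n_sites
    return all(c < thresh for c in changed[-window:])


@dataclasses.dataclass
class SamplerConfig:
    """Run-level sampler settings (see module docstring for semantics)."""

    alpha: float = 1.0
    lam: float = 1.0
    max_iterations: int = 200
    window: int = 3
    connectivity: int = 4
    scan: str = "raster"
    init: str = "per_site"
    mu0: float | None = None
    kappa0: float = 0.01
    a0: float = 2.0
    b0: float | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.scan not in ("raster", "random"):
            raise ValueError("scan must be 'raster' or 'random'")
        if self.init not in ("per_site", "single"):
            raise ValueError("init must be 'per_site' or 'single'")

    def base_measure(self, values: np.ndarray) -> BaseMeasure:
        b = BaseMeasure.from_data(values, kappa0=self.kappa0, a0=self.a0)
        return BaseMeasure(
            mu0=self.mu0 if self.mu0 is not None else b.mu0,
            kappa0=self.kappa0, a0=self.a0,
            b0=self.b0 if self.b0 is not None else b.b0)


def run_sampler(image: IntensityImage, config: SamplerConfig | None = None,
                rng: np.random.Generator | int | None = None
                ) -> tuple[LabelField, SamplerTrace]:
    """Segment an image: Gibbs sweeps until the burn-in rule or the cap.

    Starts (by default) from one cluster per site — clusters then emerge
    by merging — sweeps at most ``config.max_iterations`` times (default
    200) and stops early once :func:`has_converged` fires.  Deterministic
    for a fixed seed/Generator.
    """
    if config is None:
        config = SamplerConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    valid = image.valid_mask().ravel()
    base = config.base_measure(image.pixels.ravel()[valid])
    state = SamplerState.from_image(image, alpha=config.alpha, lam=config.lam,
                                    base=base, connectivity=config.connectivity,
                                    init=config.init)
    trace = SamplerTrace()
    n_sites = state.n_sites
    raster = np.flatnonzero(state.labels >= 0)
    for it in range(config.max_iterations):
        order = raster if config.scan == "raster" else rng.permutation(raster)
        state, n_changed = gibbs_sweep(state, rng, order=order)
        trace.append(it, state.n_clusters, n_changed)
        if has_converged(trace, n_sites, config.window):
            break
    return state.label_field(), trace


class DPMRFSegmenter:
    """DP-mixture image clustering with MRF label smoothing, sklearn-style.

    fit(X) runs the collapsed Gibbs sampler on a 2-D intensity array (or
    :class:`~dpmseg.image_io.IntensityImage`) and exposes

    labels_ : 2-D int array of cluster labels (-1 outside the mask)
    n_clusters_ : number of clusters at the terminating sweep
    trace_ : :class:`SamplerTrace` of the chain
    n_iter_ : number of sweeps actually run
    """

    def __init__(self, alpha: float = 1.0, lam: float = 1.0,
                 max_iterations: int = 200, window: int = 3,
                 connectivity: int = 4, scan: str = "raster",
                 init: str = "per_site",
                 mu0: float | None = None, kappa0: float = 0.01,
                 a0: float = 2.0, b0: float | None = None,
                 random_state: int | None = 0):
        self.alpha = alpha
        self.lam = lam
        self.max_iterations = max_iterations
        self.window = window
        self.connectivity = connectivity
        self.scan = scan
        self.init = init
        self.mu0 = mu0
        self.kappa0 = kappa0
        self.a0 = a0
        self.b0 = b0
        self.random_state = random_state

    _param_names = ("alpha", "lam", "max_iterations", "window", "connectivity",
                    "scan", "init", "mu0", "kappa0", "a0", "b0", "random_state")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> SamplerConfig:
        return SamplerConfig(alpha=self.alpha, lam=self.lam,
                             max_iterations=self.max_iterations,
                             window=self.window,
                             connectivity=self.connectivity, scan=self.scan,
                             init=self.init, mu0=self.mu0, kappa0=self.kappa0,
                             a0=self.a0, b0=self.b0)

    def fit(self, X, y=None, mask: np.ndarray | None = None):
        img = X if isinstance(X, IntensityImage) else IntensityImage(
            np.asarray(X, dtype=float), mask=mask)
        rng = np.random.default_rng(self.random_state)
        field, trace = run_sampler(img, self._config(), rng)
        self.labels_ = field.labels
        self.n_clusters_ = field.n_clusters
        self.trace_ = trace
        self.n_iter_ = len(trace)
        return self

    def fit_predict(self, X, y=None, mask: np.ndarray | None = None) -> np.ndarray:
        return self.fit(X, mask=mask).labels_
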