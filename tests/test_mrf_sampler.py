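import math

import numpy as np
import pytest

from dpmseg.dp_core import BaseMeasure, ComponentStats, predictive_logdensity
from dpmseg.image_io import IntensityImage, LabelField
from dpmseg.mrf_sampler import (
    DPMRFSegmenter,
    NeighborhoodGraph,
    SamplerConfig,
    SamplerState,
    SamplerTrace,
    SmoothnessParam,
    _detach,
    binary_cost,
    gibbs_sweep,
    has_converged,
    quadratic_cost,
    run_sampler,
    site_conditional,
)


def brute_force_conditional(state, site_flat, lam=None):
    """Explicit-loop oracle: CRP prior x exp(-binary cost) x predictive."""
    lam = state.lam if lam is None else lam
    K = state.n_clusters
    comps = state.components()
    n_rest = int(state.comp_n.sum())
    x = state.data[site_flat]
    nbrs = state.graph.neighbors(site_flat)
    w = np.zeros(K + 1)
    for k in range(K):
        if comps[k].n == 0:
            continue
        h = 0.0
        for j, l in enumerate(nbrs):
            if state.labels[l] == k:
                h -= lam * 1.0
        w[k] = (comps[k].n / (n_rest + state.alpha) * math.exp(-h)
                * math.exp(predictive_logdensity(x, comps[k], state.base)))
    w[K] = (state.alpha / (n_rest + state.alpha)
            * math.exp(predictive_logdensity(x, ComponentStats(), state.base)))
    return w / w.sum()


def random_state(rng, shape=(4, 4), lam=1.0, n_labels=3):
    img = IntensityImage(rng.normal(10, 4, shape))
    state = SamplerState.from_image(img, alpha=1.2, lam=lam)
    labels = rng.integers(0, n_labels, size=state.labels.shape)
    state.labels = labels.astype(np.int64)
    state.recompute_stats()
    return state


class TestNeighborhoodGraph:
    @pytest.mark.parametrize("connectivity,deg", [(4, 4), (8, 8)])
    def test_symmetry_and_no_self_loops(self, connectivity, deg):
        g = NeighborhoodGraph.from_grid((5, 6), connectivity=connectivity)
        for i in range(30):
            nbrs = g.neighbors(i)
            assert i not in nbrs
            assert len(nbrs) <= deg
            for l in nbrs:
                assert i in g.neighbors(int(l))

    def test_interior_corner_degrees(self):
        g = NeighborhoodGraph.from_grid((3, 3))
        assert len(g.neighbors(4)) == 4  # center
        assert len(g.neighbors(0)) == 2  # corner

    def test_masked_sites_have_no_edges(self):
        mask = np.ones((3, 3), dtype=bool)
        mask[1, 1] = False
        g = NeighborhoodGraph.from_grid((3, 3), mask=mask)
        assert len(g.neighbors(4)) == 0
        assert 4 not in g.neighbors(1)


class TestCosts:
    def test_no_matching_neighbor_zero_cost(self):
        labels = LabelField(np.array([[0, 0], [0, 0]]))
        g = NeighborhoodGraph.from_grid((2, 2))
        assert binary_cost(labels, (0, 0), 5, SmoothnessParam(2.0), g) == 0.0

    def test_two_matches_half_lambda(self):
        labels = LabelField(np.array([[9, 1], [1, 9]]))
        g = NeighborhoodGraph.from_grid((2, 2))
        # neighbors of (0,0) are (0,1)=1 and (1,0)=1: two matches of label 1
        assert binary_cost(labels, (0, 0), 1, 0.5, g) == pytest.approx(-1.0)

    def test_lambda_zero_always_zero(self):
        labels = LabelField(np.array([[1, 1], [1, 1]]))
        g = NeighborhoodGraph.from_grid((2, 2))
        assert binary_cost(labels, (1, 1), 1, 0.0, g) == 0.0

    def test_quadratic_examples_and_loop_oracle(self, rng):
        g = NeighborhoodGraph.from_grid((3, 3))
        theta = np.full((3, 3), 2.5)
        assert quadratic_cost(theta, (1, 1), 2.5, g) == 0.0
        theta2 = np.zeros((3, 3))
        theta2[0, 1] = 3.0
        # site (0,0) has neighbors (0,1)=3 and (1,0)=0: candidate 0 -> 9
        assert quadratic_cost(theta2, (0, 0), 0.0, g) == pytest.approx(9.0)
        theta3 = rng.normal(size=(3, 3))
        cand = 0.7
        expected = sum((cand - theta3.ravel()[l]) ** 2
                       for l in g.neighbors(4))
        assert quadratic_cost(theta3, (1, 1), cand, g) == pytest.approx(expected)


class TestSiteConditional:
    def test_lambda_zero_equals_pure_crp_predictive(self, rng):
        for _ in range(20):
            state = random_state(rng, lam=0.0)
            site = int(rng.integers(0, 16))
            _detach(state, site)
            p = site_conditional(state, site)
            ref = brute_force_conditional(state, site, lam=0.0)
            assert np.abs(p - ref).max() < 1e-12

    def test_matches_brute_force_with_mrf(self, rng):
        for _ in range(20):
            state = random_state(rng, shape=(2, 2), lam=0.8, n_labels=2)
            for site in range(4):
                st_copy = random_state(rng, shape=(2, 2), lam=0.8, n_labels=2)
                _detach(st_copy, site)
                p = site_conditional(st_copy, site)
                ref = brute_force_conditional(st_copy, site)
                assert np.abs(p - ref).max() < 1e-12

    def test_new_cluster_mass_independent_of_lambda(self, rng):
        from dpmseg.mrf_sampler import _site_log_masses

        state1 = random_state(rng, lam=1.0)
        state2 = SamplerState.from_image(
            IntensityImage(state1.data.reshape(state1.graph.shape)),
            alpha=state1.alpha, lam=10.0, base=state1.base)
        state2.labels = state1.labels.copy()
        state2.recompute_stats()
        site = 5
        _detach(state1, site)
        _detach(state2, site)
        lw1 = _site_log_masses(state1, site)
        lw2 = _site_log_masses(state2, site)
        assert lw1[-1] == pytest.approx(lw2[-1], rel=1e-14)

    def test_requires_detached_site(self, rng):
        state = random_state(rng)
        with pytest.raises(RuntimeError, match="detached"):
            site_conditional(state, 3)


class TestGibbsSweep:
    def test_deterministic_given_seed(self, rng):
        img = IntensityImage(rng.normal(0, 1, (8, 8)))
        out = []
        for _ in range(2):
            state = SamplerState.from_image(img, alpha=1.0, lam=0.5)
            g = np.random.default_rng(77)
            for _ in range(3):
                gibbs_sweep(state, g)
            out.append(state.labels.copy())
        np.testing.assert_array_equal(out[0], out[1])

    def test_stats_match_recompute_after_sweeps(self):
        rng = np.random.default_rng(3)
        # integer intensities keep incremental stats exactly representable
        img = IntensityImage(rng.integers(0, 256, (10, 10)).astype(float))
        state = SamplerState.from_image(img, alpha=1.0, lam=1.0)
        g = np.random.default_rng(5)
        for _ in range(4):
            gibbs_sweep(state, g)
            saved = (state.comp_n.copy(), state.comp_sum.copy(),
                     state.comp_sumsq.copy())
            state.recompute_stats()
            np.testing.assert_array_equal(saved[0], state.comp_n)
            np.testing.assert_array_equal(saved[1], state.comp_sum)
            np.testing.assert_array_equal(saved[2], state.comp_sumsq)

    def test_degenerate_constant_image_keeps_valid_state(self):
        img = IntensityImage(np.full((6, 6), 3.0))
        state = SamplerState.from_image(img, alpha=50.0, lam=0.0)
        g = np.random.default_rng(0)
        for _ in range(3):
            gibbs_sweep(state, g)
            state.check_consistency()
            assert state.comp_n.sum() == 36
            assert (state.comp_n > 0).all()  # compaction removed empties

    def test_changed_count_bounded_by_sites(self, rng):
        img = IntensityImage(rng.normal(0, 1, (6, 6)))
        state = SamplerState.from_image(img)
        _, changed = gibbs_sweep(state, np.random.default_rng(1))
        assert 0 <= changed <= 36


class TestConvergenceRule:
    def test_rule_fires_on_stable_tail(self):
        trace = SamplerTrace()
        for i, ch in enumerate([500, 50, 3, 2, 2]):
            trace.append(i, 1, ch)
        assert has_converged(trace, n_sites=400, window=3)

    def test_rule_rejects_recent_large_change(self):
        trace = SamplerTrace()
        for i, ch in enumerate([500, 50, 5]):
            trace.append(i, 1, ch)
        assert not has_converged(trace, n_sites=400, window=3)

    def test_all_zero_trace_converged(self):
        trace = SamplerTrace()
        for i in range(3):
            trace.append(i, 1, 0)
        assert has_converged(trace, n_sites=10, window=3)

    def test_short_trace_not_converged(self):
        trace = SamplerTrace()
        trace.append(0, 1, 0)
        assert not has_converged(trace, n_sites=10, window=3)


class TestRunSampler:
    def two_plateau_image(self):
        arr = np.where(np.arange(12) < 6, 10.0, 200.0)[None, :] * np.ones((12, 1))
        return IntensityImage(arr)

    @pytest.mark.parametrize("lam", [0.0, 1.0])
    def test_exact_recovery_on_two_plateaus(self, lam):
        img = self.two_plateau_image()
        labels, _ = run_sampler(img, SamplerConfig(alpha=1.0, lam=lam),
                                np.random.default_rng(0))
        assert labels.n_clusters == 2
        left = labels.labels[:, :6]
        right = labels.labels[:, 6:]
        assert len(np.unique(left)) == 1 and len(np.unique(right)) == 1
        assert left[0, 0] != right[0, 0]

    def test_trace_records_every_iteration(self):
        img = self.two_plateau_image()
        _, trace = run_sampler(img, SamplerConfig(max_iterations=7, window=100),
                               np.random.default_rng(0))
        assert trace.iterations == list(range(7))
        assert all(k >= 1 for k in trace.n_clusters)

    def test_deterministic_for_fixed_seed(self, rng):
        img = IntensityImage(rng.normal(50, 10, (10, 10)))
        l1, t1 = run_sampler(img, SamplerConfig(), np.random.default_rng(9))
        l2, t2 = run_sampler(img, SamplerConfig(), np.random.default_rng(9))
        np.testing.assert_array_equal(l1.labels, l2.labels)
        assert t1.n_changed == t2.n_changed

    def test_never_exceeds_cap(self, rng):
        img = IntensityImage(rng.normal(0, 1, (8, 8)))
        _, trace = run_sampler(img, SamplerConfig(), np.random.default_rng(2))
        assert len(trace) <= 200

    def test_masked_sites_keep_sentinel_label(self, rng):
        mask = np.ones((8, 8), dtype=bool)
        mask[:2] = False
        img = IntensityImage(rng.normal(0, 1, (8, 8)), mask=mask)
        labels, _ = run_sampler(img, SamplerConfig(), np.random.default_rng(0))
        assert (labels.labels[:2] == -1).all()
        assert (labels.labels[2:] >= 0).all()


class TestSegmenterEstimator:
    def test_fit_sets_fitted_attributes(self, small_phantom):
        est = DPMRFSegmenter(random_state=0)
        est.fit(small_phantom.t1c)
        assert est.labels_.shape == (32, 32)
        assert est.n_clusters_ >= 1
        assert est.n_iter_ == len(est.trace_)

    def test_fit_predict_equals_labels(self, small_phantom):
        est = DPMRFSegmenter(random_state=0)
        out = est.fit_predict(small_phantom.t1c)
        np.testing.assert_array_equal(out, est.labels_)

    def test_get_set_params_roundtrip(self):
        est = DPMRFSegmenter()
        params = est.get_params()
        params["lam"] = 2.5
        est.set_params(**params)
        assert est.lam == 2.5

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = DPMRFSegmenter(alpha=2.0, lam=0.3)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
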