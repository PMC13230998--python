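"""Tests for random-walk hit rates and the stability protocols."""

import numpy as np
import pytest
import scipy.sparse as sp

import umitopo as ut


def path_graph():
    """L1 - L2 - H chain with unit weights."""
    a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    labels = ut.InformationLabels(high=np.array([False, False, True]),
                                  depth_threshold=0.0)
    return sp.csr_matrix(a), labels


def random_weighted_graph(rng, n):
    a = np.triu((rng.random((n, n)) < 0.35) * rng.random((n, n)), k=1)
    a = a + a.T
    return sp.csr_matrix(a)


class TestLabelByDepth:
    def test_strict_split(self):
        pop = _toy_pop([10_000, 10_001])
        labels = ut.label_by_depth(pop, 10_000)
        assert labels.high.tolist() == [False, True]

    def test_degenerate_sides_warn(self):
        pop = _toy_pop([5, 6])
        with pytest.warns(UserWarning):
            assert ut.label_by_depth(pop, 0).n_high == 2
        with pytest.warns(UserWarning):
            assert ut.label_by_depth(pop, 6).n_low == 2


def _toy_pop(depths):
    depths = np.asarray(depths, dtype=np.int64)
    return ut.CellPopulation(
        counts=sp.csc_matrix(depths[None, :]),
        labels=np.array(["S"] * depths.size),
        depths=depths,
        provenance={},
    )


class TestExactHitProbability:
    def test_path_fixture_matrix_powers(self):
        g, labels = path_graph()
        prob = ut.exact_hit_probability(g, labels, 5)
        assert np.allclose(prob, [3 / 4, 7 / 8])

    def test_zero_steps_and_monotonicity(self):
        g, labels = path_graph()
        assert np.allclose(ut.exact_hit_probability(g, labels, 0), 0)
        probs = [ut.exact_hit_probability(g, labels, k) for k in range(6)]
        for a, b in zip(probs, probs[1:]):
            assert np.all(b >= a - 1e-12)

    def test_isolated_low_vertex_never_hits(self):
        a = np.zeros((3, 3))
        a[1, 2] = a[2, 1] = 1.0
        labels = ut.InformationLabels(high=np.array([False, False, True]),
                                      depth_threshold=0.0)
        prob = ut.exact_hit_probability(sp.csr_matrix(a), labels, 5)
        assert prob[0] == 0 and prob[1] > 0


class TestComputeHitRate:
    def test_path_fixture_monte_carlo(self):
        g, labels = path_graph()
        table = ut.compute_hit_rate(g, labels, k_walk=5, trials=1_000, rng=0)
        for rate, p in zip(table.rates, [3 / 4, 7 / 8]):
            assert abs(rate - p) < 4 * np.sqrt(p * (1 - p) / 1_000)

    def test_forced_outcomes(self):
        # low cell adjacent only to high cells hits on the first step;
        # a low-only component never hits
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0  # low 0 - high 1
        a[2, 3] = a[3, 2] = 1.0  # low 2 - low 3
        labels = ut.InformationLabels(
            high=np.array([False, True, False, False]), depth_threshold=0.0
        )
        table = ut.compute_hit_rate(sp.csr_matrix(a), labels, trials=200, rng=1)
        rates = dict(zip(table.low_indices, table.rates))
        assert rates[0] == 1.0
        assert rates[2] == 0.0 and rates[3] == 0.0

    def test_agrees_with_exact_on_random_graphs(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 10:
            n = int(rng.integers(6, 21))
            g = random_weighted_graph(rng, n)
            high = rng.random(n) < 0.4
            if high.all() or not high.any():
                continue
            labels = ut.InformationLabels(high=high, depth_threshold=0.0)
            exact = ut.exact_hit_probability(g, labels, 5)
            mc = ut.compute_hit_rate(g, labels, k_walk=5, trials=1_000,
                                     rng=int(rng.integers(2**31)))
            tol = 4 * np.sqrt(exact * (1 - exact) / 1_000) + 1e-9
            assert np.all(np.abs(mc.rates - exact) <= tol)
            checked += 1


class TestSpearman:
    def _table(self, rates):
        return ut.HitRateTable(low_indices=np.arange(len(rates)),
                               rates=np.asarray(rates, dtype=float),
                               k_walk=5, trials=1_000)

    def test_perfect_monotone(self):
        rho, _ = ut.spearman_hitrate_vs_depth(self._table([0.1, 0.2, 0.3]),
                                              np.array([1, 2, 3]))
        assert rho == pytest.approx(1.0)
        rho, _ = ut.spearman_hitrate_vs_depth(self._table([0.3, 0.2, 0.1]),
                                              np.array([1, 2, 3]))
        assert rho == pytest.approx(-1.0)

    def test_tied_ranks_match_hand_formula(self):
        # depths (1,1,2) -> average ranks (1.5,1.5,3); rates strictly increasing
        rho, _ = ut.spearman_hitrate_vs_depth(self._table([0.1, 0.2, 0.3]),
                                              np.array([1, 1, 2]))
        assert rho == pytest.approx(np.sqrt(3) / 2, abs=1e-12)

    def test_constant_input_is_undefined(self):
        rho, p = ut.spearman_hitrate_vs_depth(self._table([0.5, 0.5, 0.5]),
                                              np.array([1, 2, 3]))
        assert np.isnan(rho) and np.isnan(p)


class TestRemovalCurve:
    @pytest.fixture(scope="class")
    def setup(self, small_z):
        cfg = ut.WorkflowConfig(seed=4)
        res = ut.run_standard_workflow(small_z.counts, cfg)
        labels = ut.label_by_depth(small_z, 4_000)
        table = ut.compute_hit_rate(res.connectivities, labels, rng=4)
        return small_z, cfg, table

    def test_fraction_zero_keeps_everything(self, setup):
        pop, cfg, table = setup
        curve = ut.progressive_removal_curve(pop, table, cfg, fractions=[0.0])
        assert curve.kept_indices[0].size == pop.n_cells

    def test_endpoint_equals_depth_filter(self, setup):
        pop, cfg, table = setup
        curve = ut.progressive_removal_curve(pop, table, cfg, fractions=[1.0])
        expected = np.flatnonzero(pop.depths > 4_000)
        assert np.array_equal(np.sort(curve.kept_indices[0]), expected)
        direct = ut.abstraction_topology(ut.filter_by_total_umi(pop, 4_000), cfg)[1]
        assert curve.summaries[0].beta1 == direct.beta1

    def test_rejects_bad_fractions(self, setup):
        pop, cfg, table = setup
        with pytest.raises(ValueError):
            ut.progressive_removal_curve(pop, table, cfg, fractions=[1.5])


class TestSubsampleBeta1:
    def test_full_population_single_draw(self, small_z):
        cfg = ut.WorkflowConfig(seed=0)
        dist = ut.subsample_beta1(small_z, n_cells=small_z.n_cells, repeats=1,
                                  config=cfg, rng=9)
        direct = ut.abstraction_topology(
            small_z, ut.WorkflowConfig(seed=int(dist.seeds[0]))
        )[1]
        assert dist.beta1[0] == direct.beta1
        assert dist.beta1.dtype.kind == "i" and np.all(dist.beta1 >= 0)

    def test_oversized_subsample_rejected(self, small_z):
        with pytest.raises(ValueError):
            ut.subsample_beta1(small_z, n_cells=small_z.n_cells + 1, repeats=1)


class TestHyperparameterSweep:
    def test_tidy_output_and_determinism(self, small_z):
        grid = [{"neighbor_fraction": 0.02, "resolution": 1.0, "k_walk": 3}]
        kwargs = dict(
            depth_threshold=4_000, n_cells=200, repeats=2, trials=50,
            base_config=ut.WorkflowConfig(seed=0),
        )
        df1 = ut.hyperparameter_sweep(small_z, grid, rng=5, **kwargs)
        df2 = ut.hyperparameter_sweep(small_z, grid, rng=5, **kwargs)
        assert len(df1) == len(grid) * 3 * 2  # three population variants
        assert set(df1["population"]) == {"full", "hit50", "deep"}
        assert df1.equals(df2)
        with pytest.raises(ValueError):
            ut.hyperparameter_sweep(small_z, [], rng=0, **kwargs)
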