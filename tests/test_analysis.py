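import numpy as np
import pytest

from bfoamsa.analysis import (
    ComparisonReport,
    ConstantTraceError,
    RunSet,
    compare_runs,
    convergence_iteration,
    mean_zcurve,
    threshold_nfe,
    zscore_trace,
)
from bfoamsa.optimizers import RunTrace


def make_trace(fitness, nfe=None):
    n = len(fitness)
    return RunTrace(
        best_fitness=list(map(float, fitness)),
        best_blosum=[0.0] * n,
        best_interaction=[0.0] * n,
        nfe=list(nfe) if nfe is not None else [8 * (i + 1) for i in range(n)],
        elapsed_s=[0.0] * n,
    )


class TestZscore:
    def test_hand_computed_three_points(self):
        z = zscore_trace(make_trace([1, 2, 3]))
        np.testing.assert_allclose(z, [-1.224744871, 0.0, 1.224744871], atol=1e-8)

    def test_mean_zero_std_one(self):
        rng = np.random.default_rng(5)
        z = zscore_trace(make_trace(rng.normal(50, 7, size=200)))
        assert abs(z.mean()) < 1e-12
        assert abs(z.std() - 1.0) < 1e-12

    def test_location_scale_invariance(self):
        f = np.random.default_rng(2).normal(size=50)
        np.testing.assert_allclose(
            zscore_trace(make_trace(f)), zscore_trace(make_trace(3.5 * f + 100)), atol=1e-9
        )

    def test_constant_trace_rejected(self):
        with pytest.raises(ConstantTraceError):
            zscore_trace(make_trace([4, 4, 4]))


class TestMeanZcurve:
    def test_identical_runs_equal_single_curve(self):
        t = make_trace([1, 5, 2, 8])
        curve = mean_zcurve(RunSet([t] * 30))
        np.testing.assert_allclose(curve, zscore_trace(t), atol=1e-12)

    def test_matches_brute_force_average(self):
        rng = np.random.default_rng(11)
        traces = [make_trace(rng.normal(size=40)) for _ in range(10)]
        brute = np.mean([zscore_trace(t) for t in traces], axis=0)
        np.testing.assert_allclose(mean_zcurve(RunSet(traces)), brute, atol=1e-12)

    def test_antisymmetric_pair_cancels(self):
        f = np.array([1.0, 3.0, 2.0, 5.0])
        curve = mean_zcurve([make_trace(f), make_trace(-f)])
        np.testing.assert_allclose(curve, 0.0, atol=1e-12)

    def test_constant_run_error_names_run(self):
        with pytest.raises(ConstantTraceError, match="run 1"):
            mean_zcurve([make_trace([1, 2, 3]), make_trace([7, 7, 7])])


class TestConvergence:
    def test_first_crossing(self):
        assert convergence_iteration(make_trace([0, 50, 95, 100]), 0.95) == 2

    def test_frac_one_is_argmax(self):
        assert convergence_iteration(make_trace([1, 9, 4, 2]), 1.0) == 1

    def test_running_maximum_survives_decay(self):
        # fitness worsens after its peak; the crossing iteration must not move
        assert convergence_iteration(make_trace([1, 96, 40, 30, 100]), 0.9) == 1

    def test_negative_values_use_minmax_normalization(self):
        # normalized: [0, 0.5, 0.96, 1.0]; 95% threshold crossed at index 2
        assert convergence_iteration(make_trace([-100, -50, -4, 0]), 0.95) == 2

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            f = rng.uniform(1, 100, size=30)
            frac = rng.uniform(0.5, 1.0)
            running_best, oracle = -np.inf, None
            for i, v in enumerate(f):
                running_best = max(running_best, v)
                if running_best >= frac * f.max():
                    oracle = i
                    break
            assert convergence_iteration(make_trace(f), frac) == oracle


class TestThresholdNfe:
    def test_two_single_runs_midpoint_median(self):
        a = RunSet([make_trace([5, 10])], label="a")
        b = RunSet([make_trace([15, 20])], label="b")
        res = threshold_nfe(a, b)
        assert res.thi == 15.0
        assert res.discarded_a == 1 and res.nfe_a == []
        assert res.discarded_b == 0 and len(res.nfe_b) == 1

    def test_identical_sets_are_symmetric(self):
        traces = [make_trace([1, 2, 3 + k]) for k in range(4)]
        res = threshold_nfe(RunSet(list(traces)), RunSet(list(traces)))
        assert res.nfe_a == res.nfe_b
        assert res.discarded_a == res.discarded_b

    def test_discards_exactly_below_median_runs(self):
        rng = np.random.default_rng(8)
        mk = lambda peak: make_trace(np.linspace(0, peak, 10))  # noqa: E731
        set_a = RunSet([mk(p) for p in rng.uniform(50, 100, 15)])
        set_b = RunSet([mk(p) for p in rng.uniform(0, 50, 15)])
        res = threshold_nfe(set_a, set_b)
        pooled = np.concatenate([set_a.best_fitnesses(), set_b.best_fitnesses()])
        expected_discard = int((pooled < res.thi).sum())
        assert res.discarded_a + res.discarded_b == expected_discard
        assert len(res.nfe_a) + len(res.nfe_b) + expected_discard == 30

    def test_nfe_read_at_first_crossing(self):
        t = make_trace([0, 4, 9, 9], nfe=[10, 20, 30, 40])
        res = threshold_nfe(RunSet([t]), RunSet([make_trace([0, 1, 2, 9],
                                                            nfe=[10, 20, 30, 40])]))
        assert res.thi == 9.0
        assert res.nfe_a == [30] and res.nfe_b == [40]


class TestCompareRuns:
    def test_identical_samples(self):
        a = np.random.default_rng(1).normal(size=30)
        rep = compare_runs(a, a)
        assert rep.cohens_d == 0.0
        assert not rep.significant

    def test_unit_effect_size_recovered(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 60)
        b = rng.normal(1, 1, 60)
        rep = compare_runs(a, b)
        assert rep.cohens_d == pytest.approx(1.0, abs=0.35)
        assert rep.significant

    def test_outliers_route_to_mann_whitney(self):
        rng = np.random.default_rng(7)
        a = np.concatenate([rng.normal(size=25), [60.0, 90.0, 120.0]])
        b = rng.normal(size=28)
        rep = compare_runs(a, b)
        assert rep.test == "mann_whitney_u"

    def test_normal_samples_use_welch(self):
        rng = np.random.default_rng(12)
        rep = compare_runs(rng.normal(size=40), rng.normal(size=40))
        assert rep.test == "welch_t"

    def test_zero_variance_everywhere_undefined_d(self):
        from bfoamsa.analysis import cohens_d

        with pytest.raises(ValueError):
            cohens_d([3, 3, 3], [4, 4, 4])

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_runs([1, 2], [1, 2, 3])


def test_plotting_smoke(tmp_path):
    from bfoamsa.analysis import plot_nfe_boxplot, plot_zcurves

    rng = np.random.default_rng(0)
    rs = RunSet([make_trace(rng.normal(size=20)) for _ in range(3)], label="demo")
    plot_zcurves([rs], tmp_path / "z.png")
    res = threshold_nfe(rs, rs)
    plot_nfe_boxplot(res, ("a", "b"), tmp_path / "box.png")
    assert (tmp_path / "z.png").exists() and (tmp_path / "box.png").exists()
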