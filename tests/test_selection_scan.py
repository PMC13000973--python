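import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erscan import (bh_fdr, classify_snp, cmh_test, concordance_filter,
                    delta_af)
from erscan.io_formats import ConfigError


class TestDeltaAf:
    @pytest.mark.parametrize("final,g1,expected", [
        (0.7, 0.7, 0.0),
        (1.0, 0.0, 1.0),
        (0.62, 0.30, 0.32),
    ])
    def test_signed_difference(self, final, g1, expected):
        assert delta_af(final, g1) == pytest.approx(expected)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            delta_af(1.2, 0.5)


class TestClassifySnp:
    @pytest.mark.parametrize("da,dh,expected", [
        (+0.40, +0.40, "global_adaptation"),
        (+0.40, -0.40, "antagonistic_pleiotropy"),
        (+0.10, -0.05, "background"),
        (+0.40, +0.10, "conditional_ambient"),
        (-0.10, -0.40, "conditional_hot"),
    ])
    def test_four_class_scheme_at_study_threshold(self, da, dh, expected):
        assert classify_snp(da, dh, 0.345, 0.345) == expected

    def test_regime_swap_symmetry(self):
        rng = np.random.default_rng(0)
        da, dh = rng.uniform(-1, 1, 200), rng.uniform(-1, 1, 200)
        fwd = classify_snp(da, dh, 0.3, 0.4)
        rev = classify_snp(dh, da, 0.4, 0.3)
        swap = {"conditional_ambient": "conditional_hot",
                "conditional_hot": "conditional_ambient"}
        assert all(swap.get(a, a) == b for a, b in zip(fwd, rev))

    def test_bad_threshold_raises(self):
        with pytest.raises(ValueError):
            classify_snp(0.1, 0.1, 1.5, 0.3)


class TestConcordanceFilter:
    def test_opposite_directions_fail(self):
        ok, why = concordance_filter([[+0.4, -0.4]], [[0.9, 0.9]], 0.3, 0.5)
        assert not ok[0] and why[0] == "direction"

    def test_fst_below_null_fails(self):
        ok, why = concordance_filter([[+0.4, +0.4]], [[0.9, 0.4]], 0.3, 0.5)
        assert not ok[0] and why[0] == "fst"

    def test_all_conditions_met_pass(self):
        ok, why = concordance_filter([[+0.4, +0.4]], [[0.9, 0.9]], 0.3, 0.5)
        assert ok[0] and why[0] == "pass"

    def test_subthreshold_daf_fails(self):
        ok, why = concordance_filter([[+0.2, +0.4]], [[0.9, 0.9]], 0.3, 0.5)
        assert not ok[0] and why[0] == "daf"

    def test_single_replicate_is_config_error(self):
        with pytest.raises(ConfigError):
            concordance_filter([[0.4]], [[0.9]], 0.3, 0.5)

    @given(st.floats(0.0, 0.5), st.floats(0.0, 0.5))
    @settings(deadline=None, max_examples=30)
    def test_pass_set_shrinks_as_thresholds_grow(self, thr, extra):
        rng = np.random.default_rng(42)
        daf = rng.uniform(-1, 1, (300, 2))
        fst = rng.uniform(0, 1, (300, 2))
        lo, _ = concordance_filter(daf, fst, thr, 0.2)
        hi, _ = concordance_filter(daf, fst, thr + extra, 0.2)
        assert not np.any(hi & ~lo)


class TestCmh:
    def test_no_association_gives_zero_statistic(self):
        tables = [[[10, 10], [10, 10]], [[10, 10], [10, 10]]]
        stat, p = cmh_test(tables)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_single_stratum_printed_value(self):
        stat, p = cmh_test(np.array([[[20, 0], [0, 20]]]))
        assert stat == pytest.approx(35.1975, abs=1e-4)
        assert p < 1e-8

    def test_matches_statsmodels_at_zero_drift(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(0)
        for _ in range(5):
            tabs = rng.integers(1, 40, size=(3, 2, 2))
            st_ = sm.stats.StratifiedTable(
                np.transpose(tabs, (1, 2, 0)).astype(float))
            ref = st_.test_null_odds(correction=True)
            stat, p = cmh_test(tabs)
            assert stat == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_drift_adjust_reduces_to_classic_at_zero_drift(self):
        tabs = np.array([[[30, 20], [25, 25]], [[40, 10], [25, 25]]])
        classic = cmh_test(tabs)
        adjusted = cmh_test(tabs, ne_trajectories=[], drift_adjust=True,
                            shared_ancestral=False)
        assert adjusted == pytest.approx(classic)

    def test_drift_adjust_shrinks_statistic(self):
        tabs = np.array([[[30, 20], [25, 25]], [[40, 10], [25, 25]]])
        stat0, _ = cmh_test(tabs)
        stat1, _ = cmh_test(tabs, ne_trajectories=[18] * 6, drift_adjust=True)
        assert stat1 < stat0

    def test_vectorised_equals_scalar(self):
        rng = np.random.default_rng(1)
        stack = rng.integers(1, 50, size=(20, 2, 2, 2))
        stat, p = cmh_test(stack)
        for i in range(20):
            si, pi = cmh_test(stack[i])
            assert si == pytest.approx(stat[i])
            assert pi == pytest.approx(p[i])

    def test_neutral_type_one_error_calibrated(self):
        # seeded neutral E&R experiment: drift-adjusted p-values ~ uniform
        from erscan import PoolDesign, SimConfig, simulate_er_experiment
        traj = (100,) * 6
        designs = (PoolDesign("G1", "ancestral", "ancestral", "-", 25, ()),
                   PoolDesign("EA", "hot", "generalised", "A", 25, traj),
                   PoolDesign("EB", "hot", "generalised", "B", 25, traj))
        cfg = SimConfig(designs=designs, n_chromosomes=1,
                        snps_per_chromosome=10_000, depth_mean=100, seed=21)
        sim = simulate_er_experiment(cfg)
        tabs = np.stack([
            np.stack([np.stack([sim.counts[e], sim.depths[e] - sim.counts[e]],
                               axis=-1),
                      np.stack([sim.counts["G1"],
                                sim.depths["G1"] - sim.counts["G1"]], axis=-1)],
                     axis=-2)
            for e in ("EA", "EB")], axis=1)
        _, p = cmh_test(tabs, ne_trajectories=[traj, traj],
                        pool_sizes=[25, 25], ancestral_pool_size=25,
                        drift_adjust=True)
        assert abs(np.mean(p < 0.05) - 0.05) < 0.01


class TestBhFdr:
    def test_equal_pvalues_unchanged(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_hand_stepped_example(self):
        q = bh_fdr([0.01, 0.02, 0.04, 0.8])
        assert np.allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.8])

    def test_monotone_over_sorted_order(self):
        rng = np.random.default_rng(2)
        p = rng.random(100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p)

    def test_invalid_pvalues_raise(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
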