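import numpy as np
import pytest

from erscan import (PoolDesign, SelectedLocus, SimConfig,
                    draw_founder_spectrum, pool_read_counts,
                    simulate_er_experiment, wf_step)
from erscan.drift_calibration import drift_variance
from erscan.io_formats import ConfigError


def _cfg(designs, **kw):
    return SimConfig(designs=designs, **kw)


class TestFounderSpectrum:
    def test_uniform_matches_ancestral_heterozygosity(self, small_design, rng):
        cfg = _cfg(small_design)
        p = draw_founder_spectrum(100_000, cfg, rng)
        assert p.min() >= 0.1 and p.max() <= 0.9
        # uniform(0.1, 0.9): E[p(1-p)] = 0.25 - 0.8^2/12, He = 2*E[p(1-p)] ~ 0.39
        het = 2 * p * (1 - p)
        se = het.std() / np.sqrt(het.size)
        assert abs(het.mean() - 0.39) < 3 * se + 0.005

    def test_beta_spectrum_respects_bounds(self, small_design, rng):
        cfg = _cfg(small_design, founder_spectrum="beta")
        p = draw_founder_spectrum(5000, cfg, rng)
        assert p.min() >= 0.1 and p.max() <= 0.9

    def test_maf_min_half_is_error(self, small_design):
        with pytest.raises(ConfigError):
            _cfg(small_design, maf_min=0.5)

    def test_seed_determinism(self, small_design):
        cfg = _cfg(small_design)
        a = draw_founder_spectrum(100, cfg, np.random.default_rng(5))
        b = draw_founder_spectrum(100, cfg, np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestWfStep:
    def test_absorbing_states(self, rng):
        for s in (-0.5, 0.0, 0.8):
            assert wf_step(0.0, 10, s, rng) == 0.0
            assert wf_step(1.0, 10, s, rng) == 1.0

    def test_huge_ne_means_negligible_drift(self, rng):
        p = np.full(200, 0.37)
        out = wf_step(p, 10**6, 0.0, rng)
        assert np.all(np.abs(out - p) < 0.01)

    def test_neutral_drift_variance_matches_analytic(self, rng):
        # 6 generations at Ne=18 from p=0.5: Var = 0.25*(1-(35/36)^6)
        n = 100_000
        p = np.full(n, 0.5)
        for _ in range(6):
            p = wf_step(p, 18, 0.0, rng)
        daf = p - 0.5
        expected = drift_variance(0.5, [18] * 6)
        observed = np.mean(daf**2)
        se = np.std(daf**2) / np.sqrt(n)
        assert abs(observed - expected) < 3 * se

    def test_selection_pushes_frequency_up(self, rng):
        p = np.full(20_000, 0.3)
        out = wf_step(p, 10**6, 0.5, rng)
        # deterministic response p* = p(1+s)/(1+ps)
        assert np.mean(out) == pytest.approx(0.3 * 1.5 / 1.15, abs=1e-3)


class TestPoolReadCounts:
    def test_monomorphic_stays_zero(self, rng):
        k, d = pool_read_counts(np.zeros(100), 25, 120, 0.0, rng)
        assert np.all(k == 0) and np.all(d >= 1)

    def test_frequency_unbiased(self, rng):
        p = 0.37
        k, d = pool_read_counts(np.full(10_000, p), 25, 120, 0.0, rng)
        f = k / d
        se = f.std() / np.sqrt(f.size)
        assert abs(f.mean() - p) < 3 * se

    def test_depth_mean_near_target(self, rng):
        _, d = pool_read_counts(np.full(10_000, 0.5), 25, 120.0, 0.0, rng)
        se = d.std() / np.sqrt(d.size)
        assert abs(d.mean() - 120.0) < 3 * se + 0.01  # +: depth floored at 1

    def test_error_rate_bounds(self, rng):
        with pytest.raises(ConfigError):
            pool_read_counts(np.array([0.5]), 25, 120, 0.7, rng)


class TestSimulateExperiment:
    def test_one_sync_output_per_population(self, small_sim, tmp_path):
        paths = small_sim.write(tmp_path)
        syncs = [p for p in paths.values() if str(p).endswith(".sync")]
        assert len(syncs) == 5  # 2 treatments x 2 replicates + G1

    def test_negligible_drift_and_noise_keeps_daf_small(self, rng):
        traj = (10**6,) * 6
        designs = (PoolDesign("G1", "ancestral", "ancestral", "-", 5000, ()),
                   PoolDesign("E1", "hot", "generalised", "A", 5000, traj),
                   PoolDesign("E2", "hot", "generalised", "B", 5000, traj))
        cfg = SimConfig(designs=designs, n_chromosomes=1,
                        snps_per_chromosome=300, depth_mean=10_000, seed=2)
        sim = simulate_er_experiment(cfg)
        for pid in ("E1", "E2"):
            daf = sim.counts[pid] / sim.depths[pid] - sim.counts["G1"] / sim.depths["G1"]
            assert np.all(np.abs(daf) < 0.05)

    def test_antagonistic_locus_sign_response(self):
        # s_ambient=+0.8, s_hot=-0.8 at one locus: mean dAF of the favoured
        # (minor) allele positive in ambient pools, negative in hot pools
        traj = (100,) * 6
        designs = (PoolDesign("G1", "ancestral", "ancestral", "-", 25, ()),
                   PoolDesign("CA", "ambient", "generalised", "A", 25, traj),
                   PoolDesign("HA", "hot", "generalised", "A", 25, traj))
        diffs_a, diffs_h = [], []
        for seed in range(20):
            cfg = SimConfig(designs=designs, n_chromosomes=1,
                            snps_per_chromosome=20, chromosome_length=100_000,
                            selected_loci=(SelectedLocus(7, 0.8, -0.8),),
                            depth_mean=200, seed=seed)
            sim = simulate_er_experiment(cfg)
            # polarise on the founder-minor allele, as downstream would
            sign = 1.0 if sim.founder[7] <= 0.5 else -1.0
            diffs_a.append(sign * (sim.freqs["CA"][7] - sim.founder[7]))
            diffs_h.append(sign * (sim.freqs["HA"][7] - sim.founder[7]))
        assert np.mean(diffs_a) > 0.1
        assert np.mean(diffs_h) < -0.1

    def test_truth_table_classes(self, small_sim):
        truth = small_sim.truth
        assert list(truth["expected_class"]) == ["global_adaptation",
                                                 "antagonistic_pleiotropy"]
        assert np.all(truth["pos"].to_numpy() >= 1)

    def test_replicates_share_founders_but_not_trajectories(self, small_sim):
        assert np.array_equal(small_sim.freqs["G1"], small_sim.founder)
        assert not np.array_equal(small_sim.freqs["CGA"], small_sim.freqs["CGB"])

    def test_seed_fixes_output_files(self, tmp_path, small_design):
        cfg = SimConfig(designs=small_design, n_chromosomes=1,
                        snps_per_chromosome=50, seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_er_experiment(cfg).write(d1)
        simulate_er_experiment(cfg).write(d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_block_copy_shares_trajectories(self, small_design):
        cfg = SimConfig(designs=small_design, n_chromosomes=1,
                        snps_per_chromosome=100, chromosome_length=1_000_000,
                        block_size=250_000, seed=3)
        sim = simulate_er_experiment(cfg)
        blk = sim.block_id
        f = sim.freqs["CGA"]
        for b in np.unique(blk):
            vals = f[blk == b]
            assert np.allclose(vals, vals[0])

    def test_out_of_range_selected_locus(self, small_design):
        with pytest.raises(ConfigError):
            SimConfig(designs=small_design, n_chromosomes=1,
                      snps_per_chromosome=10,
                      selected_loci=(SelectedLocus(10, 0.5, 0.5),))

    def test_neutral_variance_matches_drift_plus_sampling(self, rng):
        # planted-truth invariant: neutral empirical Var(dAF) ~ drift variance
        # + pool/read sampling variance, within Monte-Carlo error
        traj = (35,) * 6
        m, depth = 25, 100
        designs = (PoolDesign("G1", "ancestral", "ancestral", "-", m, ()),
                   PoolDesign("E", "hot", "generalised", "A", m, traj))
        cfg = SimConfig(designs=designs, n_chromosomes=1,
                        snps_per_chromosome=30_000, depth_mean=depth, seed=4)
        sim = simulate_er_experiment(cfg)
        f1 = sim.counts["E"] / sim.depths["E"]
        f0 = sim.counts["G1"] / sim.depths["G1"]
        daf = f1 - f0
        pq = sim.founder * (1 - sim.founder)
        d = 1 - (1 - 1 / (2 * 35)) ** 6
        expected = pq * (d + 2 * (1 / (2 * m) + 1 / depth))
        observed = np.mean(daf**2)
        se = np.std(daf**2) / np.sqrt(daf.size)
        assert abs(observed - np.mean(expected)) < 4 * se
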