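"""Synthetic generator: design arithmetic, ground-truth consistency,
cross-subject independence and determinism."""

import numpy as np
import pytest

from isfcnet import simulate as sim


class TestBlockRegressor:
    def test_boxcar_occupancy_single_condition(self):
        # 7 blocks of 10 s at TR 2 s -> 7 x 5 = 35 active samples of 56
        cfg = sim.SimConfig(n_subjects_per_group=1, n_nodes=2, n_timepoints=56,
                            n_conditions=1, n_block_reps=7)
        box = sim.boxcar_design(cfg, 1)
        assert box.shape == (1, 56)
        assert box.sum() == 35

    def test_zero_blocks_gives_zero_regressor(self):
        cfg = sim.SimConfig(n_subjects_per_group=1, n_nodes=2, n_timepoints=56,
                            n_conditions=1, n_block_reps=0)
        reg = sim.generate_block_regressor(cfg, 1)
        assert np.all(reg == 0)

    def test_design_longer_than_scan_rejected(self):
        cfg = sim.SimConfig(n_subjects_per_group=1, n_nodes=2, n_timepoints=50,
                            n_conditions=1, n_block_reps=7)
        with pytest.raises(ValueError, match="exceeds scan duration"):
            sim.boxcar_design(cfg, 1)

    def test_hrf_kernel_peaks_4_to_6_seconds(self):
        t = np.arange(0, 32, 0.1)
        h = sim.hrf_double_gamma(t)
        assert 4.0 <= t[np.argmax(h)] <= 6.0
        # late undershoot dips below zero
        assert h[t > 12].min() < 0

    def test_regressor_shape_and_conditions_interleaved(self):
        cfg = sim.SimConfig(n_subjects_per_group=1, n_nodes=2, n_timepoints=120,
                            n_conditions=3, n_block_reps=5)
        box = sim.boxcar_design(cfg, 3)
        assert np.all(box.sum(axis=0) <= 1)  # no overlap
        reg = sim.generate_block_regressor(cfg, 3)
        assert reg.shape == (3, 120)


class TestPanel:
    def test_same_seed_bit_identical(self, small_config):
        p1, _ = sim.generate_panel(small_config)
        p2, _ = sim.generate_panel(small_config)
        assert np.array_equal(p1.data, p2.data)

    def test_different_seed_differs(self, small_config):
        import dataclasses
        p1, _ = sim.generate_panel(small_config)
        p2, _ = sim.generate_panel(dataclasses.replace(small_config, seed=99))
        assert not np.array_equal(p1.data, p2.data)

    def test_noise_free_subjects_identical_within_group(self, quiet_artifacts):
        cfg = sim.SimConfig(n_subjects_per_group=3, n_nodes=4, n_timepoints=120,
                            n_conditions=2, n_block_reps=3, intrinsic_sd=0.0,
                            artifact_params=quiet_artifacts, seed=1)
        panel, _ = sim.generate_panel(cfg)
        ctrl = panel.group_panel("control")
        assert np.allclose(ctrl.data[0], ctrl.data[1])
        assert np.allclose(ctrl.data[0], ctrl.data[2])

    def test_ground_truth_matches_empirical_stimulus_correlation(self, quiet_artifacts):
        mixing = sim.planted_pair_mixing(8, 4, r_a=0.6, r_b=0.25)
        cfg = sim.SimConfig(n_subjects_per_group=2, n_nodes=8, n_timepoints=2000,
                            n_conditions=4, intrinsic_sd=0.0,
                            stim_mixing={"control": mixing["a"], "cp": mixing["b"]},
                            artifact_params=quiet_artifacts, seed=5)
        panel, truth = sim.generate_panel(cfg)
        for g in ("control", "cp"):
            emp = np.corrcoef(panel.group_panel(g).data[0])
            assert np.abs(emp - truth.stimulus_locked_corr[g]).max() < 0.05

    def test_ground_truth_matrices_valid_correlations(self, small_config):
        _, truth = sim.generate_panel(small_config)
        for c in truth.stimulus_locked_corr.values():
            assert np.allclose(c, c.T)
            assert np.allclose(np.diag(c), 1.0)
            assert np.linalg.eigvalsh(c).min() > -1e-10

    def test_planted_edge_listed_with_correct_delta(self, small_config):
        _, truth = sim.generate_panel(small_config)
        assert len(truth.planted_diff_edges) == 1
        i, j, dr, dz = truth.planted_diff_edges[0]
        assert (i, j) == (0, 1)
        assert dr == pytest.approx(0.5)
        assert dz == pytest.approx(np.arctanh(0.7) - np.arctanh(0.2))

    def test_intrinsic_only_panels_independent_across_subjects(self, quiet_artifacts):
        cfg = sim.SimConfig(n_subjects_per_group=3, n_nodes=5, n_timepoints=2000,
                            n_conditions=2, n_block_reps=3, stim_sd=0.0,
                            intrinsic_sd=1.0, artifact_params=quiet_artifacts, seed=9)
        panel, _ = sim.generate_panel(cfg)
        T = cfg.n_timepoints
        rs = []
        for a in range(panel.n_subjects):
            for b in range(a + 1, panel.n_subjects):
                for n in range(cfg.n_nodes):
                    rs.append(np.corrcoef(panel.data[a, n], panel.data[b, n])[0, 1])
        assert abs(np.mean(rs)) < 2.0 / np.sqrt(T)

    def test_invalid_spatial_corr_rejected(self):
        with pytest.raises(ValueError, match="intrinsic_spatial_corr"):
            sim.SimConfig(intrinsic_spatial_corr=1.0)

    def test_mismatched_mixing_shape_rejected(self):
        with pytest.raises(ValueError, match="mixing"):
            sim.SimConfig(n_nodes=4, n_conditions=2,
                          stim_mixing={"control": np.zeros((3, 2)),
                                       "cp": np.zeros((4, 2))})


class TestVolume:
    def test_noise_free_blob_matches_seed(self, rng):
        seeds = rng.standard_normal((2, 100))
        data, labels, _ = sim.generate_volume((14, 6, 6), seeds, 0.0, seed=1)
        for k in range(2):
            vox = data[labels == k + 1]
            for v in vox[:5]:
                assert np.corrcoef(v, seeds[k])[0, 1] == pytest.approx(1.0)

    def test_background_uncorrelated(self, rng):
        seeds = rng.standard_normal((2, 200))
        data, labels, _ = sim.generate_volume((14, 6, 6), seeds, 0.5, seed=2)
        bg = data[labels == 0]
        r = [abs(np.corrcoef(bg[i], seeds[0])[0, 1]) for i in range(20)]
        assert max(r) < 0.5

    def test_overlapping_blobs_rejected(self, rng):
        seeds = rng.standard_normal((2, 50))
        sl = (slice(1, 4), slice(1, 4), slice(1, 4))
        with pytest.raises(ValueError, match="overlap"):
            sim.generate_volume((8, 8, 8), seeds, 0.1, seed=3, blob_slices=[sl, sl])

    def test_determinism(self, rng):
        seeds = rng.standard_normal((2, 50))
        d1, l1, _ = sim.generate_volume((14, 6, 6), seeds, 0.3, seed=7)
        d2, l2, _ = sim.generate_volume((14, 6, 6), seeds, 0.3, seed=7)
        assert np.array_equal(d1, d2) and np.array_equal(l1, l2)


class TestBehavior:
    def test_noiseless_group_effect_separates_groups(self, small_config):
        panel, truth = sim.generate_panel(small_config)
        table = sim.generate_behavior(panel, truth, coeffs=(0.0, -6.0, 0.0),
                                      noise_sd=0.0, seed=1, measure_corr=1.0)
        ctrl = table[table.group == "control"]
        cp = table[table.group == "cp"]
        assert ctrl["famous_faces_pct"].min() > cp["famous_faces_pct"].max()
        assert ctrl["cfmt_pct"].min() > cp["cfmt_pct"].max()

    def test_measure_correlation_near_target(self):
        # Fisher-z sampling at n = 20 puts ~94% of sample r within +-0.25 of 0.7
        mixing = sim.planted_pair_mixing(6, 3, r_a=0.7, r_b=0.2)
        cfg = sim.SimConfig(n_subjects_per_group=10, n_nodes=6, n_timepoints=120,
                            n_conditions=3, n_block_reps=5,
                            stim_mixing={"control": mixing["a"], "cp": mixing["b"]},
                            seed=11)
        panel, truth = sim.generate_panel(cfg)
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            t = sim.generate_behavior(panel, truth, noise_sd=0.5, seed=rep,
                                      measure_corr=0.7)
            r = np.corrcoef(t["famous_faces_pct"], t["cfmt_pct"])[0, 1]
            hits += abs(r - 0.7) <= 0.25
        assert hits >= 0.9 * n_rep

    def test_negative_noise_rejected(self, small_config):
        panel, truth = sim.generate_panel(small_config)
        with pytest.raises(ValueError, match="noise_sd"):
            sim.generate_behavior(panel, truth, noise_sd=-1.0, seed=0)

    def test_determinism(self, small_config):
        panel, truth = sim.generate_panel(small_config)
        t1 = sim.generate_behavior(panel, truth, seed=4)
        t2 = sim.generate_behavior(panel, truth, seed=4)
        assert t1.equals(t2)
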