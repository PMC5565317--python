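"""Edge-wise t-tests, permutation null, empirical p and FDR masks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isfcnet import difference as dfn
from isfcnet import simulate as sim
from isfcnet.connectivity import TimeSeriesPanel
from conftest import brute_force_isfc


def _edge_stack(values):
    """Per-subject 2-node matrices carrying one edge value each."""
    out = []
    for v in values:
        m = np.array([[0.0, v], [v, 0.0]])
        out.append(m)
    return np.stack(out)


class TestTTest:
    def test_hand_computed_pooled_t(self):
        # A = {1,2,3}, B = {4,5,6}: means 2 and 5, pooled sd 1 -> t = -3.674
        t = dfn.edgewise_ttest(_edge_stack([1, 2, 3]), _edge_stack([4, 5, 6]))
        assert t[0, 1] == pytest.approx(-3.6742346, abs=1e-6)

    def test_identical_groups_zero(self, rng):
        stack = rng.standard_normal((3, 4, 4))
        stack = stack + stack.transpose(0, 2, 1)
        t = dfn.edgewise_ttest(stack, stack.copy())
        assert np.allclose(t, 0.0)

    def test_group_swap_antisymmetry(self, rng):
        a = rng.standard_normal((4, 3, 3))
        b = rng.standard_normal((5, 3, 3))
        a, b = a + a.transpose(0, 2, 1), b + b.transpose(0, 2, 1)
        assert np.allclose(dfn.edgewise_ttest(a, b), -dfn.edgewise_ttest(b, a))

    def test_degenerate_group_size_rejected(self, rng):
        a = rng.standard_normal((1, 3, 3))
        with pytest.raises(ValueError, match="at least 2"):
            dfn.edgewise_ttest(a, a)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_scipy_oracle(self, seed):
        from scipy import stats
        r = np.random.default_rng(seed)
        a = _edge_stack(r.standard_normal(4))
        b = _edge_stack(r.standard_normal(6))
        t = dfn.edgewise_ttest(a, b)
        expect = stats.ttest_ind(a[:, 0, 1], b[:, 0, 1], equal_var=True).statistic
        assert t[0, 1] == pytest.approx(expect, abs=1e-10)


class TestPermutationNull:
    def test_fixed_seed_reproducible(self, rng):
        stack = rng.standard_normal((8, 3, 3))
        stack = stack + stack.transpose(0, 2, 1)
        n1 = dfn.permutation_null(stack, (4, 4), n_perm=50, seed=3, mode="fc")
        n2 = dfn.permutation_null(stack, (4, 4), n_perm=50, seed=3, mode="fc")
        assert np.array_equal(n1.null_t, n2.null_t)

    def test_exchangeable_null_centered(self, rng):
        stack = rng.standard_normal((12, 4, 4))
        stack = stack + stack.transpose(0, 2, 1)
        null = dfn.permutation_null(stack, (6, 6), n_perm=400, seed=0, mode="fc")
        se = null.null_t.std(axis=0) / np.sqrt(null.n_perm)
        assert np.all(np.abs(null.null_t.mean(axis=0)) < 3.5 * se + 1e-9)

    def test_isfc_mode_matches_brute_force(self, rng):
        data = rng.standard_normal((8, 4, 30))
        panel = TimeSeriesPanel(data=data, subject_ids=[f"s{i}" for i in range(8)],
                                groups=["x"] * 8, tr_s=2.0)
        null = dfn.permutation_null(panel, (4, 4), n_perm=5, seed=7, mode="isfc")
        # replay the same relabelings with an independently coded oracle
        rng2 = np.random.default_rng(7)
        iu = np.triu_indices(4, k=1)
        for p in range(5):
            perm = rng2.permutation(8)
            za = brute_force_isfc(data[perm[:4]])
            zb = brute_force_isfc(data[perm[4:]])
            t = dfn.edgewise_ttest(za, zb)
            assert np.allclose(null.null_t[p], t[iu], atol=1e-10)

    def test_exhaustive_enumerates_all_relabelings(self, rng):
        stack = rng.standard_normal((6, 3, 3))
        stack = stack + stack.transpose(0, 2, 1)
        null = dfn.permutation_null(stack, (3, 3), mode="fc", exhaustive=True)
        assert null.n_perm == 20  # C(6,3)

    def test_exhaustive_vs_monte_carlo_p(self, rng):
        # tiny 6-subject null: empirical p from enumeration vs sampling
        stack = rng.standard_normal((6, 4, 4))
        stack = stack + stack.transpose(0, 2, 1)
        t_obs = dfn.edgewise_ttest(stack[:3], stack[3:])
        exact = dfn.permutation_null(stack, (3, 3), mode="fc", exhaustive=True)
        mc = dfn.permutation_null(stack, (3, 3), n_perm=2000, seed=1, mode="fc")
        p_exact = dfn.empirical_p_and_fdr(t_obs, exact).p_pos
        p_mc = dfn.empirical_p_and_fdr(t_obs, mc).p_pos
        iu = np.triu_indices(4, k=1)
        # undo the +1 smoothing so both are exceedance proportions, then
        # compare within binomial error of the Monte-Carlo draw
        for pe, pm in zip(p_exact[iu], p_mc[iu]):
            prop_exact = (pe * 21 - 1) / 20.0
            prop_mc = (pm * 2001 - 1) / 2000.0
            se = np.sqrt(max(prop_exact * (1 - prop_exact), 0.05) / 2000)
            assert abs(prop_exact - prop_mc) < 4 * se + 2.0 / 2000

    def test_bad_args_rejected(self, rng):
        stack = rng.standard_normal((6, 3, 3))
        stack = stack + stack.transpose(0, 2, 1)
        with pytest.raises(ValueError, match="n_perm"):
            dfn.permutation_null(stack, (3, 3), n_perm=0, mode="fc")
        with pytest.raises(ValueError, match="sum"):
            dfn.permutation_null(stack, (3, 4), n_perm=5, mode="fc")


class TestEmpiricalP:
    def _null(self, null_t):
        return dfn.PermutationNull(null_t=null_t, n_nodes=2, n_perm=null_t.shape[0],
                                   seed=0, mode="fc")

    def test_observed_above_all_null_hits_floor(self):
        null = self._null(np.linspace(-1, 1, 99)[:, None])
        t_obs = np.array([[0.0, 5.0], [5.0, 0.0]])
        net = dfn.empirical_p_and_fdr(t_obs, null)
        assert net.p_pos[0, 1] == pytest.approx(1.0 / 100.0)
        assert net.p_neg[0, 1] == pytest.approx(1.0)

    def test_bh_by_hand(self):
        # p = {0.001, 0.2, 0.9} -> BH q = {0.003, 0.3, 0.9}: only edge 1 passes
        from statsmodels.stats.multitest import multipletests
        q = multipletests([0.001, 0.2, 0.9], method="fdr_bh")[1]
        assert np.allclose(q, [0.003, 0.3, 0.9])

    def test_direction_swap_symmetry(self, rng):
        stack = rng.standard_normal((8, 4, 4))
        stack = stack + stack.transpose(0, 2, 1)
        t_obs = dfn.edgewise_ttest(stack[:4], stack[4:])
        null = dfn.permutation_null(stack, (4, 4), n_perm=200, seed=5, mode="fc")
        net = dfn.empirical_p_and_fdr(t_obs, null)
        flipped = dfn.PermutationNull(null_t=-null.null_t, n_nodes=4,
                                      n_perm=null.n_perm, seed=5, mode="fc")
        net2 = dfn.empirical_p_and_fdr(-t_obs, flipped)
        assert np.array_equal(net.sig_pos, net2.sig_neg)
        assert np.array_equal(net.sig_neg, net2.sig_pos)
        assert np.allclose(net.p_pos, net2.p_neg)

    def test_p_bounds(self, rng):
        stack = rng.standard_normal((8, 5, 5))
        stack = stack + stack.transpose(0, 2, 1)
        t_obs = dfn.edgewise_ttest(stack[:4], stack[4:])
        null = dfn.permutation_null(stack, (4, 4), n_perm=99, seed=2, mode="fc")
        net = dfn.empirical_p_and_fdr(t_obs, null)
        iu = np.triu_indices(5, k=1)
        for p in (net.p_pos[iu], net.p_neg[iu]):
            assert np.all(p > 0) and np.all(p <= 1)

    def test_long_format_frame(self, rng):
        stack = rng.standard_normal((6, 4, 4))
        stack = stack + stack.transpose(0, 2, 1)
        t_obs = dfn.edgewise_ttest(stack[:3], stack[3:])
        null = dfn.permutation_null(stack, (3, 3), n_perm=20, seed=0, mode="fc")
        frame = dfn.empirical_p_and_fdr(t_obs, null).to_frame()
        assert len(frame) == 6  # C(4,2) undirected edges
        assert (frame["node_i"] < frame["node_j"]).all()


class TestPlantedDifference:
    def test_planted_edge_detected_and_directional(self):
        mixing = sim.planted_pair_mixing(8, 4, r_a=0.75, r_b=0.1)
        cfg = sim.SimConfig(n_subjects_per_group=6, n_nodes=8, n_timepoints=240,
                            n_conditions=4, intrinsic_sd=0.5,
                            stim_mixing={"control": mixing["a"], "cp": mixing["b"]},
                            seed=21)
        panel, truth = sim.generate_panel(cfg)
        from isfcnet.connectivity import isfc_matrices, preprocess
        clean = preprocess(panel)
        a, _ = isfc_matrices(clean.group_panel("control"))
        b, _ = isfc_matrices(clean.group_panel("cp"))
        t_obs = dfn.edgewise_ttest(a, b)
        null = dfn.permutation_null(clean, (6, 6), n_perm=200, seed=3, mode="isfc")
        net = dfn.empirical_p_and_fdr(t_obs, null)
        i, j, _, _ = truth.planted_diff_edges[0]
        iu = np.triu_indices(8, k=1)
        assert net.p_pos[i, j] == net.p_pos[iu].min()  # strongest control>cp edge
        assert net.p_pos[i, j] <= 0.05
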