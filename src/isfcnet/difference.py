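"""Directional group-difference networks with a subject-relabeling null.

For every node pair an independent-samples t-test compares the two groups'
Fisher-z edge values; positive t means group A > group B.  Statistical
significance is assessed against a permutation null in which subjects are
relabeled into groups of the original sizes and the whole estimator — for
ISFC, the entire leave-one-out construction within each permuted group —
is recomputed.  Directional empirical p-values (with the standard +1
smoothing so p is never zero) are corrected across edges per direction
with the Benjamini-Hochberg false-discovery-rate procedure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .connectivity import EdgeMatrix, TimeSeriesPanel, _isfc_values

__all__ = [
    "DifferenceNetwork",
    "PermutationNull",
    "edgewise_ttest",
    "permutation_null",
    "empirical_p_and_fdr",
]


def _as_stack(mats) -> np.ndarray:
    if isinstance(mats, np.ndarray):
        stack = mats
    else:
        stack = np.stack([m.values if isinstance(m, EdgeMatrix) else np.asarray(m)
                          for m in mats])
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("expected a stack of square per-subject matrices")
    return stack


def _ttest_stack(a: np.ndarray, b: np.ndarray, welch: bool) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    if welch:
        denom = np.sqrt(va / na + vb / nb)
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    t[(denom == 0) & (diff == 0)] = 0.0  # identical degenerate edges
    return t


def edgewise_ttest(matrices_a, matrices_b, *, welch: bool = False) -> np.ndarray:
    """Two-sample t statistic per edge on Fisher-z values (A minus B).

    Pooled-variance Student t by default; set ``welch`` for unequal
    variances.  The diagonal is zeroed (excluded from inference).
    """
    a, b = _as_stack(matrices_a), _as_stack(matrices_b)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("group matrices differ in node count")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    t = _ttest_stack(a, b, welch)
    np.fill_diagonal(t, 0.0)
    return t


@dataclass
class PermutationNull:
    """Per-edge null t samples from subject relabeling."""

    null_t: np.ndarray          # (n_perm, n_edges) upper-triangle order
    n_nodes: int
    n_perm: int
    seed: int | None
    mode: str                   # "fc" | "isfc"
    exhaustive: bool = False

    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        return np.triu_indices(self.n_nodes, k=1)


def _relabelings(n_total: int, n_a: int, n_perm: int,
                 seed: int | None, exhaustive: bool):
    if exhaustive:
        for combo in itertools.combinations(range(n_total), n_a):
            idx_a = np.array(combo)
            idx_b = np.array([i for i in range(n_total) if i not in combo])
            yield idx_a, idx_b
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n_total)
            yield perm[:n_a], perm[n_a:]


def permutation_null(
    data,
    group_sizes: tuple[int, int],
    n_perm: int = 10_000,
    seed: int | None = 0,
    mode: str = "isfc",
    *,
    exhaustive: bool = False,
    welch: bool = False,
    symmetrize: bool = True,
) -> PermutationNull:
    """Null t distribution per edge under random subject relabeling.

    ``data`` is either a pooled stack of per-subject edge matrices
    (``mode="fc"``: matrices are fixed, only labels permute) or a pooled
    :class:`TimeSeriesPanel` / (S, N, T) array (``mode="isfc"``: the
    leave-one-out ISFC construction is recomputed within each permuted
    group before the t-test).  With ``exhaustive`` all C(n, n_a)
    relabelings are enumerated and ``n_perm``/``seed`` are ignored.
    """
    n_a, n_b = group_sizes
    if not exhaustive and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("fc", "isfc"):
        raise ValueError("mode must be 'fc' or 'isfc'")

    if mode == "fc":
        stack = _as_stack(data)
        n_total, n_nodes = stack.shape[0], stack.shape[1]
    else:
        arr = data.data if isinstance(data, TimeSeriesPanel) else np.asarray(data, float)
        if arr.ndim != 3:
            raise ValueError("isfc mode expects (subjects, nodes, timepoints) data")
        n_total, n_nodes = arr.shape[0], arr.shape[1]
    if n_a + n_b != n_total:
        raise ValueError("group sizes do not sum to the number of subjects")
    if min(n_a, n_b) < 2:
        raise ValueError("each group needs at least 2 subjects")

    iu = np.triu_indices(n_nodes, k=1)
    rows = []
    for idx_a, idx_b in _relabelings(n_total, n_a, n_perm, seed, exhaustive):
        if mode == "fc":
            t = _ttest_stack(stack[idx_a], stack[idx_b], welch)
        else:
            za = _isfc_values(arr[idx_a], symmetrize)
            zb = _isfc_values(arr[idx_b], symmetrize)
            t = _ttest_stack(za, zb, welch)
        rows.append(t[iu])
    null_t = np.asarray(rows)
    return PermutationNull(
        null_t=null_t,
        n_nodes=n_nodes,
        n_perm=null_t.shape[0],
        seed=None if exhaustive else seed,
        mode=mode,
        exhaustive=exhaustive,
    )


@dataclass
class DifferenceNetwork:
    """Edge-wise group contrast with directional permutation p and FDR q.

    Matrices are symmetric with zero diagonal; ``p_pos``/``q_pos`` refer to
    the A > B direction (positive t), ``p_neg``/``q_neg`` to B > A.
    """

    t: np.ndarray
    p_pos: np.ndarray
    p_neg: np.ndarray
    q_pos: np.ndarray
    q_neg: np.ndarray
    sig_pos: np.ndarray
    sig_neg: np.ndarray
    q_star: float
    n_perm: int
    seed: int | None = None
    mode: str = "isfc"

    @property
    def n_nodes(self) -> int:
        return self.t.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format edge table (each undirected edge once, i < j)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return pd.DataFrame(
            {
                "node_i": iu[0],
                "node_j": iu[1],
                "t": self.t[iu],
                "p_pos": self.p_pos[iu],
                "p_neg": self.p_neg[iu],
                "q_pos": self.q_pos[iu],
                "q_neg": self.q_neg[iu],
                "sig_pos": self.sig_pos[iu],
                "sig_neg": self.sig_neg[iu],
            }
        )


def _square(vec: np.ndarray, n: int, iu, fill: float = 0.0) -> np.ndarray:
    m = np.full((n, n), fill)
    m[iu] = vec
    m[(iu[1], iu[0])] = vec
    np.fill_diagonal(m, fill)
    return m


def empirical_p_and_fdr(
    t_obs: np.ndarray,
    null: PermutationNull,
    q_star: float = 0.05,
) -> DifferenceNetwork:
    """Directional empirical p-values and BH-FDR masks for a t matrix.

    p(A>B) = (1 + #{null >= t_obs}) / (1 + n_perm) and symmetrically for
    B > A; the +1 smoothing counts the observed relabeling among the null
    and keeps p strictly positive.  Benjamini-Hochberg is applied across
    edges separately per direction; masks flag q <= q_star.
    """
    if null.null_t.size == 0:
        raise ValueError("empty permutation null")
    n = null.n_nodes
    t_obs = np.asarray(t_obs, dtype=float)
    if t_obs.shape != (n, n):
        raise ValueError("t matrix does not match the null's node count")
    iu = null.edge_index()
    tv = t_obs[iu]
    P = null.null_t.shape[0]
    p_pos = (1.0 + (null.null_t >= tv[None, :]).sum(axis=0)) / (1.0 + P)
    p_neg = (1.0 + (null.null_t <= tv[None, :]).sum(axis=0)) / (1.0 + P)
    q_pos = multipletests(p_pos, method="fdr_bh")[1]
    q_neg = multipletests(p_neg, method="fdr_bh")[1]
    return DifferenceNetwork(
        t=t_obs,
        p_pos=_square(p_pos, n, iu, fill=1.0),
        p_neg=_square(p_neg, n, iu, fill=1.0),
        q_pos=_square(q_pos, n, iu, fill=1.0),
        q_neg=_square(q_neg, n, iu, fill=1.0),
        sig_pos=_square((q_pos <= q_star).astype(float), n, iu).astype(bool),
        sig_neg=_square((q_neg <= q_star).astype(float), n, iu).astype(bool),
        q_star=q_star,
        n_perm=P,
        seed=null.seed,
        mode=null.mode,
    )
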