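"""Topological characterization of difference networks.

All measures operate on the *non-thresholded* positive part of the group
contrast's t matrix, treated as a weighted undirected graph: node strength
(sum of positive incident weights) and its descending rank; a
posterior-to-anterior gradient (Spearman correlation between binned MNI Y
coordinate and mean node strength); enrichment of face-selective nodes
among top-ranked nodes against a base rate; and module-based measures —
within-module weighted degree z and participation coefficient (Guimera-
Amaral conventions) with module-hub / connector-hub classification —
where the modules are the three functional tags (face, nonface, mixed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "node_strength",
    "GradientResult",
    "gradient_correlation",
    "gradient_scan",
    "enrichment_chi2",
    "module_metrics",
    "classify_hubs",
]


def _positive_part(weight_matrix: np.ndarray, direction: str) -> np.ndarray:
    w = np.asarray(weight_matrix, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if direction == "positive":
        w = np.clip(w, 0.0, None)
    elif direction == "negative":
        w = np.clip(-w, 0.0, None)
    else:
        raise ValueError("direction must be 'positive' or 'negative'")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w


def node_strength(weight_matrix: np.ndarray, direction: str = "positive") -> pd.DataFrame:
    """Node strength on the positive part of a signed contrast matrix.

    ``direction="positive"`` keeps positive weights (the A > B contrast);
    ``"negative"`` negates first, giving the strength of the reverse
    contrast.  Returns a frame with ``strength`` and descending ``rank``
    (1 = strongest; ties broken by node id).
    """
    w = _positive_part(weight_matrix, direction)
    strength = w.sum(axis=1)
    n = len(strength)
    order = np.lexsort((np.arange(n), -strength))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    return pd.DataFrame({"node_id": np.arange(n), "strength": strength, "rank": rank})


# ---------------------------------------------------------------------------
# posterior-anterior gradient
# ---------------------------------------------------------------------------

@dataclass
class GradientResult:
    """Spearman association between binned Y coordinate and node strength."""

    n_bins: int
    table: pd.DataFrame     # bin, n_nodes, mean_strength
    rho: float
    p_value: float
    degenerate: bool = False  # all bin means tied; rho reported as 0


def gradient_correlation(
    y_mm: np.ndarray, strengths: np.ndarray, n_bins: int
) -> GradientResult:
    """Bin nodes by ascending MNI Y and correlate bin index with strength.

    Nodes are sorted posterior to anterior and split into ``n_bins``
    equal-count bins (when the count does not divide evenly, the most
    posterior bins receive one extra node); the Spearman correlation is
    computed between bin index and per-bin mean strength.  A positive rho
    means anterior nodes are stronger.
    """
    y = np.asarray(y_mm, dtype=float)
    s = np.asarray(strengths, dtype=float)
    if y.shape != s.shape:
        raise ValueError("y coordinates and strengths differ in length")
    n = y.size
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > n:
        raise ValueError("fewer nodes than bins")
    order = np.lexsort((np.arange(n), y))
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:rem] += 1
    bin_means, counts = [], []
    pos = 0
    for b in range(n_bins):
        chunk = order[pos: pos + sizes[b]]
        bin_means.append(s[chunk].mean())
        counts.append(len(chunk))
        pos += sizes[b]
    table = pd.DataFrame(
        {"bin": np.arange(n_bins), "n_nodes": counts, "mean_strength": bin_means}
    )
    means = np.asarray(bin_means)
    if np.allclose(means, means[0]):
        return GradientResult(n_bins, table, rho=0.0, p_value=1.0, degenerate=True)
    rho, p = stats.spearmanr(np.arange(n_bins), means)
    return GradientResult(n_bins, table, rho=float(rho), p_value=float(p))


def gradient_scan(
    y_mm: np.ndarray,
    strengths: np.ndarray,
    bin_range: range = range(10, 22),
) -> list[GradientResult]:
    """Gradient correlation over a range of bin counts (infeasible skipped)."""
    out = []
    n = len(np.asarray(y_mm))
    for n_bins in bin_range:
        if n_bins > n:
            continue
        out.append(gradient_correlation(y_mm, strengths, n_bins))
    return out


# ---------------------------------------------------------------------------
# selectivity enrichment
# ---------------------------------------------------------------------------

def enrichment_chi2(
    k_selected: int, n_top: int, base_rate: float
) -> tuple[float, float]:
    """Goodness-of-fit chi-square of a top-node tag count against a base rate.

    Compares observed counts (k, n - k) with expectation (n*b, n*(1-b)),
    df = 1, no continuity correction.  Returns (chi2, p).
    """
    if not 0.0 < base_rate < 1.0:
        raise ValueError("base_rate must lie strictly between 0 and 1")
    if not 0 <= k_selected <= n_top:
        raise ValueError("k_selected must lie in [0, n_top]")
    expected = np.array([n_top * base_rate, n_top * (1.0 - base_rate)])
    observed = np.array([k_selected, n_top - k_selected], dtype=float)
    chi2, p = stats.chisquare(observed, expected)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# module metrics and hubs
# ---------------------------------------------------------------------------

def module_metrics(
    weight_matrix: np.ndarray,
    module_labels,
    direction: str = "positive",
) -> pd.DataFrame:
    """Within-module weighted degree z-score and participation coefficient.

    Modules are categorical labels (here the functional tags).  For node i
    with positive strength s_i and strength s_im into module m:

    * participation  P_i = 1 - sum_m (s_im / s_i)^2   (0 = single-module);
    * within-module weighted degree z_i standardizes s_i,own against the
      distribution of that quantity in node i's own module.

    Degenerate cases are flagged rather than raised: isolated nodes get
    P = 0, and modules of size 1 (or zero spread) get z = 0.  The raw
    within-module strength is also returned.
    """
    labels = np.asarray(module_labels)
    w = _positive_part(weight_matrix, direction)
    n = w.shape[0]
    if labels.shape != (n,):
        raise ValueError("module labels must cover all nodes")
    modules = pd.unique(labels)
    s_total = w.sum(axis=1)
    s_by_mod = np.stack([w[:, labels == m].sum(axis=1) for m in modules], axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = s_by_mod / s_total[:, None]
    participation = 1.0 - np.nansum(frac**2, axis=1)
    isolated = s_total == 0
    participation[isolated] = 0.0

    own_col = np.array([np.where(modules == m)[0][0] for m in labels])
    s_own = s_by_mod[np.arange(n), own_col]
    wmd_z = np.zeros(n)
    z_flag = np.zeros(n, dtype=bool)
    for mi, m in enumerate(modules):
        members = labels == m
        vals = s_own[members]
        sd = vals.std()
        if members.sum() < 2 or sd == 0:
            z_flag[members] = True
            continue
        wmd_z[members] = (vals - vals.mean()) / sd
    return pd.DataFrame(
        {
            "node_id": np.arange(n),
            "module": labels,
            "strength": s_total,
            "within_module_strength": s_own,
            "within_module_degree_z": wmd_z,
            "participation": participation,
            "degenerate_module": z_flag,
            "isolated": isolated,
        }
    )


def classify_hubs(
    metrics: pd.DataFrame,
    *,
    degree_threshold: float = 2.0,
    participation_range: tuple[float, float] = (0.3, 0.75),
) -> pd.Series:
    """Hub classes from module metrics.

    A node is a ``module_hub`` when its within-module weighted degree z
    exceeds ``degree_threshold``; a module hub whose participation
    coefficient lies inside ``participation_range`` (inclusive) is promoted
    to ``connector_hub``; everything else is ``none``.
    """
    z = metrics["within_module_degree_z"].to_numpy()
    p = metrics["participation"].to_numpy()
    lo, hi = participation_range
    out = np.where(z > degree_threshold, "module_hub", "none")
    out = np.where((out == "module_hub") & (p >= lo) & (p <= hi), "connector_hub", out)
    return pd.Series(out, index=metrics.index, name="hub_class")
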