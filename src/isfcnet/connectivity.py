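"""Within-subject functional connectivity (FC) and leave-one-out inter-subject
functional correlation (ISFC).

FC correlates node time courses within one brain, so it mixes stimulus-evoked
signal with intrinsic fluctuations and non-neuronal artifacts.  ISFC instead
correlates node *i* of one subject with node *j* of the average of the
remaining subjects in the same group: components that are idiosyncratic to a
subject (intrinsic dynamics, drift, motion, respiration) cannot correlate
across brains, so ISFC isolates the stimulus-locked part of the correlation
structure.  Both estimators return Fisher z-transformed correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TimeSeriesPanel",
    "EdgeMatrix",
    "preprocess",
    "average_runs",
    "dct_highpass_basis",
    "fc_matrix",
    "fc_matrices",
    "isfc_matrices",
    "CLIP_R",
]

#: correlations are clipped to +-(1 - 1e-7) before arctanh so that degenerate
#: identical series yield a large but finite z value.
CLIP_R = 1.0 - 1e-7


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilizing Fisher transform, z = arctanh(r), with clipping."""
    return np.arctanh(np.clip(r, -CLIP_R, CLIP_R))


@dataclass
class TimeSeriesPanel:
    """Multi-subject node-by-time BOLD-like data with group labels.

    Parameters
    ----------
    data : ndarray, shape (n_subjects, n_nodes, n_timepoints)
    subject_ids : sequence of str
    groups : sequence of str, one label per subject
    tr_s : float
        Repetition time (sampling interval) in seconds.
    """

    data: np.ndarray
    subject_ids: list[str]
    groups: list[str]
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"panel data must be (subjects, nodes, timepoints); got shape {self.data.shape}"
            )
        self.subject_ids = list(self.subject_ids)
        self.groups = list(self.groups)
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("number of subject_ids does not match data")
        if len(self.groups) != self.data.shape[0]:
            raise ValueError("number of group labels does not match data")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("panel contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def group_panel(self, group: str) -> "TimeSeriesPanel":
        """Sub-panel containing only subjects of ``group`` (in original order)."""
        idx = [i for i, g in enumerate(self.groups) if g == group]
        if not idx:
            raise KeyError(f"no subjects in group {group!r}")
        return TimeSeriesPanel(
            data=self.data[idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            groups=[group] * len(idx),
            tr_s=self.tr_s,
        )


@dataclass
class EdgeMatrix:
    """Symmetric node x node matrix of Fisher-z connectivity values.

    The diagonal is excluded from every downstream statistic.  For FC it is
    set to zero; for ISFC it holds the classical inter-subject correlation of
    each node (subject vs. left-out group mean), which is occasionally useful
    diagnostically.
    """

    values: np.ndarray
    kind: str = "fc"  # "fc" | "isfc"
    subject: str | None = None
    symmetric: bool = True  # False only for un-symmetrized directional ISFC

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("edge matrix must be square")
        if self.symmetric and not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("edge matrix must be symmetric")
        if not np.all(np.isfinite(v)):
            raise ValueError("edge matrix contains non-finite values")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        """Upper-triangle (i < j) edge vector."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def dct_highpass_basis(n_timepoints: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift basis for high-pass filtering.

    Returns the DCT-II regressors whose period ``2 * T * TR / k`` is at
    least ``cutoff_s`` (the constant term excluded), as columns of a
    ``(n_timepoints, k_max)`` array.  Regressing these out removes
    fluctuations slower than the cutoff; the conventional cutoff for block
    designs is 128 s.
    """
    if cutoff_s <= 2 * tr_s:
        raise ValueError("cutoff_s must exceed twice the sampling interval")
    t = np.arange(n_timepoints)
    k_max = int(np.floor(2.0 * n_timepoints * tr_s / cutoff_s))
    basis = np.empty((n_timepoints, k_max))
    for k in range(1, k_max + 1):
        basis[:, k - 1] = np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_timepoints))
    return basis


def _zscore_rows(x: np.ndarray, what: str = "series") -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    if np.any(sd <= 0):
        raise ValueError(f"zero-variance {what} cannot be standardized")
    return (x - mu) / sd


def preprocess(panel: TimeSeriesPanel, cutoff_s: float = 128.0) -> TimeSeriesPanel:
    """Standardize and high-pass filter every node time course.

    Each series is z-scored (zero mean, unit variance), the discrete-cosine
    drift basis with periods longer than ``cutoff_s`` is regressed out, and
    the residual is re-standardized.
    """
    X = panel.data
    S, N, T = X.shape
    Z = _zscore_rows(X)
    basis = dct_highpass_basis(T, panel.tr_s, cutoff_s)
    if basis.shape[1] > 0:
        # orthonormalize once, project out the drift subspace
        q, _ = np.linalg.qr(basis)
        flat = Z.reshape(S * N, T)
        flat = flat - (flat @ q) @ q.T
        Z = flat.reshape(S, N, T)
    Z = _zscore_rows(Z, what="series after filtering")
    return replace(panel, data=Z)


def average_runs(panels: list[TimeSeriesPanel]) -> TimeSeriesPanel:
    """Element-wise mean of matched runs (same subjects, shapes and TR)."""
    if not panels:
        raise ValueError("no runs supplied")
    first = panels[0]
    for p in panels[1:]:
        if p.data.shape != first.data.shape:
            raise ValueError("run shape mismatch")
        if p.subject_ids != first.subject_ids:
            raise ValueError("runs have mismatched subjects")
        if p.tr_s != first.tr_s:
            raise ValueError("runs have mismatched TR")
    mean = np.mean([p.data for p in panels], axis=0)
    return replace(first, data=mean)


# ---------------------------------------------------------------------------
# FC
# ---------------------------------------------------------------------------

def fc_matrix(
    subject_series: np.ndarray,
    *,
    normalize: bool = True,
    subject: str | None = None,
) -> EdgeMatrix:
    """Within-subject functional connectivity for one subject.

    Pairwise Pearson correlation between node time courses, Fisher
    z-transformed.  When ``normalize`` is on (the default) the subject's
    off-diagonal edge values are additionally standardized to zero mean and
    unit variance, removing subject-level global correlation offsets.
    """
    X = np.asarray(subject_series, dtype=float)
    if X.ndim != 2:
        raise ValueError("subject series must be (nodes, timepoints)")
    if X.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    _zscore_rows(X)  # variance guard
    z = fisher_z(np.corrcoef(X))
    np.fill_diagonal(z, 0.0)
    if normalize:
        iu = np.triu_indices(z.shape[0], k=1)
        edges = z[iu]
        sd = edges.std()
        if sd <= 0:
            raise ValueError("cannot z-normalize edges with zero variance")
        edges = (edges - edges.mean()) / sd
        out = np.zeros_like(z)
        out[iu] = edges
        z = out + out.T
    return EdgeMatrix(values=z, kind="fc", subject=subject)


def fc_matrices(panel: TimeSeriesPanel, *, normalize: bool = True) -> list[EdgeMatrix]:
    """One FC matrix per subject in the panel."""
    return [
        fc_matrix(panel.data[s], normalize=normalize, subject=panel.subject_ids[s])
        for s in range(panel.n_subjects)
    ]


# ---------------------------------------------------------------------------
# ISFC
# ---------------------------------------------------------------------------

def _isfc_values(data: np.ndarray, symmetrize: bool) -> np.ndarray:
    """Leave-one-out ISFC z-matrices for one group; returns (S, N, N)."""
    S, N, T = data.shape
    if S < 2:
        raise ValueError("ISFC needs at least 2 subjects per group")
    total = data.sum(axis=0)
    out = np.empty((S, N, N))
    for s in range(S):
        mean_others = (total - data[s]) / (S - 1)
        zs = _zscore_rows(data[s])
        zm = _zscore_rows(mean_others, what="left-out group-mean series")
        r = zs @ zm.T / T
        z = fisher_z(r)
        if symmetrize:
            z = 0.5 * (z + z.T)
        out[s] = z
    return out


def isfc_matrices(
    group_panel: TimeSeriesPanel,
    *,
    symmetrize: bool = True,
    normalize: bool = False,
) -> tuple[list[EdgeMatrix], EdgeMatrix]:
    """Leave-one-out ISFC for a single group.

    For each subject ``s`` the node time courses of ``s`` are correlated with
    the element-wise mean time courses of the remaining subjects, for every
    ordered node pair (i, j); the correlations are Fisher z-transformed and,
    by default, the (i -> j) and (j -> i) directions are averaged to give a
    symmetric matrix.  The diagonal holds each node's inter-subject
    correlation.  Per-subject edge z-normalization (as applied to FC) is off
    by default for ISFC but available via ``normalize``.

    Returns the per-subject matrices and their group mean.
    """
    if len(set(group_panel.groups)) > 1:
        raise ValueError("isfc_matrices expects a single-group panel; use group_panel()")
    vals = _isfc_values(group_panel.data, symmetrize)
    if normalize:
        iu = np.triu_indices(vals.shape[1], k=1)
        for s in range(vals.shape[0]):
            edges = vals[s][iu]
            sd = edges.std()
            if sd <= 0:
                raise ValueError("cannot z-normalize edges with zero variance")
            edges = (edges - edges.mean()) / sd
            m = np.zeros_like(vals[s])
            m[iu] = edges
            vals[s] = m + m.T
    mats = [
        EdgeMatrix(
            values=vals[s],
            kind="isfc",
            subject=group_panel.subject_ids[s],
            symmetric=symmetrize,
        )
        for s in range(vals.shape[0])
    ]
    mean = EdgeMatrix(values=vals.mean(axis=0), kind="isfc", subject=None, symmetric=symmetrize)
    return mats, mean
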