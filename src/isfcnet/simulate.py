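"""Synthetic multi-subject BOLD panels with analytic ground truth.

The generator emulates a block-design visual experiment: stimulus blocks of
10 s separated by 6 s rest, 7 repetitions per block type, sampled at
TR = 2 s.  Each node's signal is the sum of three components:

* a *stimulus-locked* component shared by every subject in a group — a
  mixing matrix applied to an orthonormalized basis of HRF-convolved
  condition regressors, so the inter-node correlation of this component is
  exactly the cosine similarity of the mixing rows;
* *intrinsic* fluctuations private to each subject — AR(1) in time with an
  exchangeable cross-node correlation, which contaminates within-subject FC
  but averages out of inter-subject (ISFC) estimates;
* *non-neuronal artifacts* private to each subject — linear drift, Poisson
  spikes and a respiratory-like sinusoid shared across that subject's nodes.

Group differences are planted by giving the two groups different mixing
matrices; the implied correlation matrices and the list of differing edges
are returned as ground truth for downstream validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

__all__ = [
    "SimConfig",
    "GroundTruth",
    "hrf_double_gamma",
    "generate_block_regressor",
    "round_robin_mixing",
    "planted_pair_mixing",
    "generate_panel",
    "generate_volume",
    "generate_behavior",
    "synthetic_node_table",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ArtifactParams:
    """Per-subject non-neuronal artifact amplitudes (signal-sd units)."""

    drift_amp: float = 1.0       # peak-to-peak linear drift amplitude
    spike_rate: float = 0.01     # expected spikes per sample (Poisson)
    spike_amp: float = 3.0
    osc_amp: float = 0.3         # respiratory-like oscillation
    osc_freq_hz: float = 0.3


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic panel generator.

    ``stim_mixing`` maps each group name to an (n_nodes, n_sources) weight
    matrix applied to unit-variance, mutually orthogonal stimulus-locked
    sources (one per condition); rows of unit norm give a stimulus-locked
    component of unit variance per node.  When omitted, both groups share a
    round-robin assignment of nodes to conditions.
    """

    n_subjects_per_group: int = 10
    n_nodes: int = 30
    n_timepoints: int = 280
    tr_s: float = 2.0
    block_len_s: float = 10.0
    rest_len_s: float = 6.0
    n_block_reps: int = 7
    n_conditions: int = 5
    stim_mixing: dict[str, np.ndarray] | None = None
    stim_sd: float = 1.0
    hp_cutoff_s: float = 128.0  # analysis band; sources are built inside it
    intrinsic_sd: float = 1.0
    intrinsic_spatial_corr: float = 0.3
    ar_rho: float = 0.3
    artifact_params: ArtifactParams = field(default_factory=ArtifactParams)
    groups: tuple[str, str] = ("control", "cp")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects_per_group", "n_nodes", "n_timepoints", "n_conditions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_block_reps < 0:  # 0 = empty design, useful for null regressors
            raise ValueError("n_block_reps must be >= 0")
        if not (0.0 <= self.intrinsic_spatial_corr < 1.0):
            raise ValueError("intrinsic_spatial_corr must lie in [0, 1)")
        if not (0.0 <= self.ar_rho < 1.0):
            raise ValueError("ar_rho must lie in [0, 1)")
        if self.tr_s <= 0 or self.block_len_s <= 0 or self.rest_len_s < 0:
            raise ValueError("tr_s/block_len_s must be positive, rest_len_s non-negative")
        if self.intrinsic_sd < 0 or self.stim_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.stim_mixing is not None:
            for g, m in self.stim_mixing.items():
                m = np.asarray(m, float)
                if m.shape != (self.n_nodes, self.n_conditions):
                    raise ValueError(
                        f"mixing for group {g!r} must be "
                        f"({self.n_nodes}, {self.n_conditions}); got {m.shape}"
                    )

    def mixing_for(self, group: str) -> np.ndarray:
        if self.stim_mixing is None:
            return round_robin_mixing(self.n_nodes, self.n_conditions)
        return np.asarray(self.stim_mixing[group], dtype=float)


@dataclass
class GroundTruth:
    """Analytic quantities implied by a :class:`SimConfig`.

    ``stimulus_locked_corr`` maps group name to the node x node correlation
    matrix of the stimulus-locked component (cosine similarity of mixing
    rows).  ``planted_diff_edges`` lists (i, j, delta_r, delta_z) for edges
    whose stimulus-locked correlation differs between the two groups
    (first-listed group minus second).  ``behavior_coeffs`` is filled by
    :func:`generate_behavior`.
    """

    stimulus_locked_corr: dict[str, np.ndarray]
    planted_diff_edges: list[tuple[int, int, float, float]]
    behavior_coeffs: tuple[float, float, float] | None = None


# ---------------------------------------------------------------------------
# design / HRF
# ---------------------------------------------------------------------------

def hrf_double_gamma(
    t_s: np.ndarray,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at times ``t_s``.

    Difference of two gamma densities (shape = delay, unit scale); the
    response peaks ~5 s after a brief event and undershoots around 16 s.
    """
    pos = gamma_dist.pdf(t_s, peak_delay_s)
    neg = gamma_dist.pdf(t_s, undershoot_delay_s)
    return pos - undershoot_ratio * neg


def boxcar_design(config: SimConfig, n_conditions: int) -> np.ndarray:
    """Unconvolved per-condition boxcars, shape (n_conditions, n_timepoints).

    Conditions are interleaved without overlap: one block of each condition,
    then the next repetition, each block followed by a rest period.
    """
    if n_conditions < 1:
        raise ValueError("n_conditions must be >= 1")
    T, tr = config.n_timepoints, config.tr_s
    cycle = config.block_len_s + config.rest_len_s
    total_s = n_conditions * config.n_block_reps * cycle
    if total_s > T * tr + 1e-9:
        raise ValueError(
            f"design of {total_s:.0f}s exceeds scan duration {T * tr:.0f}s"
        )
    t = np.arange(T) * tr
    box = np.zeros((n_conditions, T))
    for rep in range(config.n_block_reps):
        for c in range(n_conditions):
            onset = (rep * n_conditions + c) * cycle
            box[c, (t >= onset) & (t < onset + config.block_len_s)] = 1.0
    return box


def generate_block_regressor(config: SimConfig, n_conditions: int) -> np.ndarray:
    """HRF-convolved block regressors, shape (n_conditions, n_timepoints).

    Boxcars from :func:`boxcar_design` convolved with the canonical
    double-gamma response sampled at the TR.  A design with zero stimulus
    blocks yields an all-zero regressor.
    """
    if config.n_block_reps == 0:
        return np.zeros((n_conditions, config.n_timepoints))
    box = boxcar_design(config, n_conditions)
    t_hrf = np.arange(0, 32.0 + config.tr_s, config.tr_s)
    hrf = hrf_double_gamma(t_hrf)
    out = np.empty_like(box)
    for c in range(n_conditions):
        out[c] = np.convolve(box[c], hrf)[: config.n_timepoints]
    return out


def stimulus_sources(config: SimConfig) -> np.ndarray:
    """Orthonormalized stimulus-locked sources, shape (n_sources, T).

    The HRF-convolved condition regressors are mean-centered, restricted to
    the analysis band (the discrete-cosine drift space below
    ``1 / hp_cutoff_s`` is projected out, mirroring the preprocessing
    filter) and orthonormalized by QR in condition order (signs fixed so
    each source correlates positively with its own regressor), then scaled
    to unit sample variance.  A mixing matrix M applied to these sources
    yields a stimulus component with covariance exactly M M', and the
    high-pass filter of the analysis leaves that covariance intact.
    """
    from .connectivity import dct_highpass_basis

    reg = generate_block_regressor(config, config.n_conditions)
    centered = reg - reg.mean(axis=1, keepdims=True)
    drift = dct_highpass_basis(config.n_timepoints, config.tr_s, config.hp_cutoff_s)
    if drift.shape[1] > 0:
        qd, _ = np.linalg.qr(drift)
        centered = centered - (centered @ qd) @ qd.T
    q, rr = np.linalg.qr(centered.T)  # (T, K)
    diag = np.diag(rr)
    if np.any(np.abs(diag) < 1e-10):
        raise ValueError("degenerate design: condition regressors are collinear")
    q = q * np.sign(diag)
    return (q * np.sqrt(config.n_timepoints)).T


# ---------------------------------------------------------------------------
# mixing-matrix constructors
# ---------------------------------------------------------------------------

def round_robin_mixing(n_nodes: int, n_sources: int) -> np.ndarray:
    """Unit loading of node k on source k mod n_sources."""
    m = np.zeros((n_nodes, n_sources))
    m[np.arange(n_nodes), np.arange(n_nodes) % n_sources] = 1.0
    return m


def planted_pair_mixing(
    n_nodes: int,
    n_sources: int,
    r_a: float,
    r_b: float,
    edge: tuple[int, int] = (0, 1),
) -> dict[str, np.ndarray]:
    """Two mixing matrices that differ only in one edge's correlation.

    Nodes ``edge = (i, j)`` load on two private sources such that their
    stimulus-locked correlation is ``r_a`` in the first matrix and ``r_b``
    in the second; all remaining nodes are uncorrelated with i and j and
    load on the leftover sources.  With at least two leftover sources the
    remaining nodes are spread over graded angles in that subspace, giving
    a realistic range of background stimulus correlations instead of
    saturated duplicates; with exactly one they all share it.  Requires
    ``n_sources >= 3``.  Keys of the returned dict are "a" and "b";
    callers map them onto group names.
    """
    if n_sources < 3:
        raise ValueError("need at least 3 sources (2 private + 1 shared)")
    i, j = edge
    if i == j:
        raise ValueError("edge must join two distinct nodes")
    out = {}
    for key, r in (("a", r_a), ("b", r_b)):
        if not -1.0 < r < 1.0:
            raise ValueError("target correlation must lie in (-1, 1)")
        m = np.zeros((n_nodes, n_sources))
        others = [n for n in range(n_nodes) if n not in (i, j)]
        for k, n in enumerate(others):
            if n_sources >= 4 and len(others) > 1:
                theta = 0.5 * np.pi * k / (len(others) - 1)
                m[n, 2] = np.cos(theta)
                m[n, 3] = np.sin(theta)
            else:
                m[n, 2] = 1.0
        m[i, 0] = 1.0
        m[j, 0] = r
        m[j, 1] = np.sqrt(1.0 - r * r)
        out[key] = m
    return out


def mixing_correlation(mixing: np.ndarray) -> np.ndarray:
    """Stimulus-locked correlation implied by a mixing matrix (cosine of rows)."""
    norms = np.linalg.norm(mixing, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    c = (mixing / safe[:, None]) @ (mixing / safe[:, None]).T
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


# ---------------------------------------------------------------------------
# panel generation
# ---------------------------------------------------------------------------

def _ar1_noise(rng: np.random.Generator, n_nodes: int, T: int,
               rho: float, spatial_corr: float) -> np.ndarray:
    """Unit-variance AR(1) noise with exchangeable cross-node correlation."""
    c = spatial_corr
    shared = rng.standard_normal(T)
    private = rng.standard_normal((n_nodes, T))
    innov = np.sqrt(c) * shared[None, :] + np.sqrt(1.0 - c) * private
    if rho == 0.0:
        return innov
    x = np.empty_like(innov)
    x[:, 0] = innov[:, 0]
    for t in range(1, T):
        x[:, t] = rho * x[:, t - 1] + np.sqrt(1.0 - rho * rho) * innov[:, t]
    return x


def _artifacts(rng: np.random.Generator, n_nodes: int, T: int, tr_s: float,
               p: ArtifactParams) -> np.ndarray:
    """Subject-global artifact time course broadcast to all nodes."""
    t = np.arange(T) * tr_s
    drift = p.drift_amp * rng.normal() * np.linspace(-0.5, 0.5, T)
    spikes = np.zeros(T)
    n_spikes = rng.poisson(p.spike_rate * T)
    if n_spikes > 0:
        pos = rng.integers(0, T, size=n_spikes)
        spikes[pos] += p.spike_amp * rng.choice([-1.0, 1.0], size=n_spikes)
    phase = rng.uniform(0, 2 * np.pi)
    osc = p.osc_amp * np.sin(2 * np.pi * p.osc_freq_hz * t + phase)
    return np.broadcast_to(drift + spikes + osc, (n_nodes, T)).copy()


from . import connectivity as _conn  # noqa: E402  (panel container)


def generate_panel(config: SimConfig) -> tuple["_conn.TimeSeriesPanel", GroundTruth]:
    """Simulate a two-group multi-subject panel plus its ground truth.

    Identical seeds produce bit-identical panels; intrinsic and artifact
    components are drawn from per-subject RNG sub-streams and are therefore
    statistically independent across subjects.
    """
    sources = stimulus_sources(config)
    corr = {g: mixing_correlation(config.mixing_for(g)) for g in config.groups}
    ga, gb = config.groups
    za, zb = np.arctanh(np.clip(corr[ga], -_conn.CLIP_R, _conn.CLIP_R)), \
        np.arctanh(np.clip(corr[gb], -_conn.CLIP_R, _conn.CLIP_R))
    planted = []
    for i in range(config.n_nodes):
        for j in range(i + 1, config.n_nodes):
            dr = corr[ga][i, j] - corr[gb][i, j]
            if abs(dr) > 1e-12:
                planted.append((i, j, float(dr), float(za[i, j] - zb[i, j])))

    ss = np.random.SeedSequence(config.seed)
    subject_streams = ss.spawn(2 * config.n_subjects_per_group)

    data = np.empty(
        (2 * config.n_subjects_per_group, config.n_nodes, config.n_timepoints)
    )
    subject_ids, group_labels = [], []
    s_idx = 0
    for g in config.groups:
        signal = config.stim_sd * (config.mixing_for(g) @ sources)
        for k in range(config.n_subjects_per_group):
            rng = np.random.default_rng(subject_streams[s_idx])
            noise = config.intrinsic_sd * _ar1_noise(
                rng, config.n_nodes, config.n_timepoints,
                config.ar_rho, config.intrinsic_spatial_corr,
            )
            art = _artifacts(rng, config.n_nodes, config.n_timepoints,
                             config.tr_s, config.artifact_params)
            data[s_idx] = signal + noise + art
            subject_ids.append(f"{g}-{k + 1:02d}")
            group_labels.append(g)
            s_idx += 1

    panel = _conn.TimeSeriesPanel(
        data=data, subject_ids=subject_ids, groups=group_labels, tr_s=config.tr_s
    )
    return panel, GroundTruth(stimulus_locked_corr=corr, planted_diff_edges=planted)


def synthetic_node_table(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Plausible node metadata (MNI-mm centers, voxel counts, tags) for a panel.

    Y coordinates are spread over the posterior-anterior range of ventral
    visual cortex; tags follow the node's dominant source in the first
    group's mixing matrix (source 0 -> face, source 1 -> nonface, later
    sources alternate; zero rows -> mixed).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    m = config.mixing_for(config.groups[0])
    tags = []
    for row in np.abs(m):
        if row.max() <= 0:
            tags.append("mixed")
        else:
            tags.append(["face", "nonface"][int(np.argmax(row)) % 2])
    return pd.DataFrame(
        {
            "node_id": np.arange(config.n_nodes),
            "x_mm": rng.uniform(-60, 60, config.n_nodes).round(1),
            "y_mm": np.sort(rng.uniform(-100, 20, config.n_nodes)).round(1),
            "z_mm": rng.uniform(-30, 10, config.n_nodes).round(1),
            "voxel_count": rng.integers(10, 60, config.n_nodes),
            "tag": tags,
        }
    )


# ---------------------------------------------------------------------------
# toy voxel volumes
# ---------------------------------------------------------------------------

def generate_volume(
    grid_dims: tuple[int, int, int],
    seed_signals: np.ndarray,
    noise_sd: float,
    seed: int,
    *,
    blob_slices: list[tuple[slice, slice, slice]] | None = None,
    blob_size: int = 4,
):
    """Toy 4D volume with >= 2 disjoint signal blobs on a noise background.

    Voxels inside blob k follow ``seed_signals[k]`` plus Gaussian noise of
    scale ``noise_sd``; background voxels are pure unit-variance noise.
    Returns ``(data, labels, affine)`` where ``labels`` is 0 for background
    and k+1 inside blob k, and ``affine`` maps grid indices to MNI mm
    (3 mm isotropic, grid-centered).
    """
    seed_signals = np.atleast_2d(np.asarray(seed_signals, dtype=float))
    K, T = seed_signals.shape
    if K < 2:
        raise ValueError("need at least 2 seed signals / blobs")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    nx, ny, nz = grid_dims
    if blob_slices is None:
        blob_slices = []
        x0 = 1
        for _ in range(K):
            if x0 + blob_size > nx - 1:
                raise ValueError("grid too small for the requested blobs")
            blob_slices.append(
                (slice(x0, x0 + blob_size), slice(1, 1 + blob_size), slice(1, 1 + blob_size))
            )
            x0 += blob_size + 2
    if len(blob_slices) != K:
        raise ValueError("one blob slice required per seed signal")

    labels = np.zeros(grid_dims, dtype=int)
    for k, sl in enumerate(blob_slices):
        if np.any(labels[sl] != 0):
            raise ValueError("blobs overlap")
        labels[sl] = k + 1

    rng = np.random.default_rng(seed)
    data = rng.standard_normal((nx, ny, nz, T))
    for k in range(K):
        inside = labels == k + 1
        n_in = int(inside.sum())
        data[inside] = seed_signals[k][None, :] + noise_sd * rng.standard_normal((n_in, T))
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    affine[:3, 3] = -1.5 * np.array(grid_dims)
    return data, labels, affine


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def generate_behavior(
    panel: "_conn.TimeSeriesPanel",
    ground_truth: GroundTruth,
    coeffs: tuple[float, float, float] = (1.0, -6.0, 5.0),
    noise_sd: float = 0.5,
    seed: int = 0,
    *,
    edge_values: np.ndarray | None = None,
    measure_corr: float = 0.7,
) -> pd.DataFrame:
    """Per-subject behavior table generated from a linear model.

    The latent composite score is ``intercept + group_effect * group_code +
    edge_effect * edge_value + noise`` with group codes 0 (first group) and
    1 (second group).  ``edge_values`` defaults to each subject's ISFC z on
    the first planted difference edge (computed within the subject's own
    group); pass an explicit array to override.  Two observed measures are
    derived from the composite with inter-measure correlation
    ``measure_corr`` and mapped onto percent-correct scales; the latent
    composite is retained in column ``composite_true`` for recovery tests.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not 0.0 < measure_corr <= 1.0:
        raise ValueError("measure_corr must lie in (0, 1]")
    intercept, group_eff, edge_eff = coeffs
    groups = panel.group_names()
    codes = np.array([groups.index(g) for g in panel.groups], dtype=float)

    if edge_values is None:
        if not ground_truth.planted_diff_edges:
            raise ValueError("no planted difference edge; pass edge_values explicitly")
        i, j, _, _ = ground_truth.planted_diff_edges[0]
        edge_values = np.empty(panel.n_subjects)
        for g in groups:
            sub = panel.group_panel(g)
            mats, _ = _conn.isfc_matrices(sub)
            idx = [k for k, gg in enumerate(panel.groups) if gg == g]
            for pos, k in enumerate(idx):
                edge_values[k] = mats[pos].values[i, j]
    edge_values = np.asarray(edge_values, dtype=float)
    if edge_values.shape != (panel.n_subjects,):
        raise ValueError("edge_values must have one entry per subject")

    rng = np.random.default_rng(seed)
    composite = (
        intercept + group_eff * codes + edge_eff * edge_values
        + noise_sd * rng.standard_normal(panel.n_subjects)
    )
    sd_c = composite.std()
    if measure_corr < 1.0 and sd_c > 0:
        eps_sd = sd_c * np.sqrt(1.0 / measure_corr - 1.0)
    else:
        eps_sd = 0.0
    m1 = composite + eps_sd * rng.standard_normal(panel.n_subjects)
    m2 = composite + eps_sd * rng.standard_normal(panel.n_subjects)
    famous = np.clip(70.0 + 4.0 * m1, 0.0, 100.0)
    cfmt = np.clip(65.0 + 4.0 * m2, 0.0, 100.0)

    ground_truth.behavior_coeffs = (float(intercept), float(group_eff), float(edge_eff))
    return pd.DataFrame(
        {
            "subject_id": panel.subject_ids,
            "group": panel.groups,
            "famous_faces_pct": famous,
            "cfmt_pct": cfmt,
            "edge_value": edge_values,
            "composite_true": composite,
        }
    )
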