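"""Run configuration for the end-to-end pipeline, with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

from . import io as _io
from .simulate import ArtifactParams, SimConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All numeric knobs of the pipeline stages plus the master seed.

    Defaults mirror the study design the simulator emulates: two groups of
    ten subjects, TR 2 s, 10 s blocks with 6 s rest and 7 repetitions,
    1/128 Hz high-pass cutoff, 10,000 relabeling permutations and a
    directional FDR threshold q* = 0.05 (0.005 for the stricter variant).
    """

    # simulation
    n_subjects_per_group: int = 10
    n_nodes: int = 30
    n_timepoints: int = 280
    tr_s: float = 2.0
    block_len_s: float = 10.0
    rest_len_s: float = 6.0
    n_block_reps: int = 7
    n_conditions: int = 5
    stim_sd: float = 1.0
    intrinsic_sd: float = 1.0
    intrinsic_spatial_corr: float = 0.3
    ar_rho: float = 0.3
    planted_edge_delta_z: float = 0.4
    planted_edge_base_r: float = 0.3
    # preprocessing / connectivity
    cutoff_s: float = 128.0
    normalize_fc_edges: bool = True
    normalize_isfc_edges: bool = False
    symmetrize_isfc: bool = True
    # parcellation
    r_threshold: float = 0.5
    max_clusters: int = 500
    min_size: int = 10
    neighborhood: int = 6
    # group difference
    n_perm: int = 10_000
    q_star: float = 0.05
    welch: bool = False
    # topology
    bins_min: int = 10
    bins_max: int = 21
    face_base_rate: float = 0.35
    hub_degree_threshold: float = 2.0
    hub_participation_min: float = 0.3
    hub_participation_max: float = 0.75
    # behavior
    behavior_coeffs: tuple[float, float, float] = (1.0, -6.0, 5.0)
    behavior_noise_sd: float = 0.5
    measure_corr: float = 0.7
    # plumbing
    seed: int = 0
    stages: tuple[str, ...] = (
        "simulate", "connectivity", "difference", "topology", "behavior",
    )

    def __post_init__(self) -> None:
        if not (0 < self.q_star <= 1) and self.q_star != 0.0:
            raise ValueError("q_star must lie in [0, 1]")
        if not (1 <= self.bins_min <= self.bins_max):
            raise ValueError("bins range must satisfy 1 <= bins_min <= bins_max")
        if not (0 < self.face_base_rate < 1):
            raise ValueError("face_base_rate must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 < self.r_threshold <= 1):
            raise ValueError("r_threshold must lie in (0, 1]")

    def sim_config(self, stim_mixing=None) -> SimConfig:
        return SimConfig(
            n_subjects_per_group=self.n_subjects_per_group,
            n_nodes=self.n_nodes,
            n_timepoints=self.n_timepoints,
            tr_s=self.tr_s,
            block_len_s=self.block_len_s,
            rest_len_s=self.rest_len_s,
            n_block_reps=self.n_block_reps,
            n_conditions=self.n_conditions,
            stim_mixing=stim_mixing,
            stim_sd=self.stim_sd,
            intrinsic_sd=self.intrinsic_sd,
            intrinsic_spatial_corr=self.intrinsic_spatial_corr,
            ar_rho=self.ar_rho,
            artifact_params=ArtifactParams(),
            seed=self.seed,
        )

    def to_yaml(self, path: str | Path) -> Path:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["behavior_coeffs"] = list(self.behavior_coeffs)
        return _io.save_yaml(d, path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = _io.load_yaml(path)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "behavior_coeffs" in d:
            d["behavior_coeffs"] = tuple(d["behavior_coeffs"])
        return cls(**d)
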