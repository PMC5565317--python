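"""End-to-end driver: simulate -> connectivity -> difference -> topology ->
behavior, writing every stage product plus a run manifest.

The whole run is deterministic given the config seed: stage RNG streams are
spawned from one master ``SeedSequence`` so stages can be toggled without
perturbing one another's randomness.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behavior as bhv, difference as diff, io as _io
from . import simulate as sim
from . import topology as topo
from .config import RunConfig
from .connectivity import fc_matrices, isfc_matrices, preprocess

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the configured stages into ``out_dir``; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("simulate", "difference", "behavior"), ss.spawn(3)
        )
    }
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {**asdict(config), "stages": list(config.stages)},
        "stage_seeds": stage_seeds,
        "outputs": {},
    }

    def record(stage: str, path: Path) -> None:
        manifest["outputs"][f"{stage}:{path.name}"] = _sha256(path)

    order = ("simulate", "connectivity", "difference", "topology", "behavior")
    requested = [s for s in config.stages if s in order]
    if not requested:
        raise PipelineError("no recognized stages requested")
    last = max(order.index(s) for s in requested)

    def finish() -> dict:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        return manifest

    stage = "simulate"
    try:
        mixing = sim.planted_pair_mixing(
            config.n_nodes,
            config.n_conditions,
            r_a=np.tanh(
                np.arctanh(config.planted_edge_base_r) + config.planted_edge_delta_z
            ),
            r_b=config.planted_edge_base_r,
        )
        sim_cfg = config.sim_config(
            stim_mixing={"control": mixing["a"], "cp": mixing["b"]}
        )
        sim_cfg.seed = stage_seeds["simulate"]
        panel, truth = sim.generate_panel(sim_cfg)
        nodes = sim.synthetic_node_table(sim_cfg)
        panel_dir = _io.write_panel(panel, out / "panel")
        manifest["panel_dir"] = str(panel_dir)
        node_path = _io.write_node_table(nodes, out / "nodes.tsv")
        record(stage, node_path)
        if last == 0:
            return finish()

        stage = "connectivity"
        clean = preprocess(panel, cutoff_s=config.cutoff_s)
        per_group_isfc = {}
        for g in clean.group_names():
            mats, mean = isfc_matrices(
                clean.group_panel(g),
                symmetrize=config.symmetrize_isfc,
                normalize=config.normalize_isfc_edges,
            )
            per_group_isfc[g] = mats
            record(stage, _io.write_edge_matrix(mean, out / f"isfc_mean_{g}.tsv"))
        for s, m in enumerate(fc_matrices(clean, normalize=config.normalize_fc_edges)):
            if s == 0:  # keep one FC example on disk; CLI `fc` writes all
                record(stage, _io.write_edge_matrix(m, out / f"fc_{m.subject}.tsv"))
        if last == 1:
            return finish()

        stage = "difference"
        ga, gb = clean.group_names()
        t_obs = diff.edgewise_ttest(
            per_group_isfc[ga], per_group_isfc[gb], welch=config.welch
        )
        null = diff.permutation_null(
            clean,
            group_sizes=(
                sum(g == ga for g in clean.groups),
                sum(g == gb for g in clean.groups),
            ),
            n_perm=config.n_perm,
            seed=stage_seeds["difference"],
            mode="isfc",
            welch=config.welch,
            symmetrize=config.symmetrize_isfc,
        )
        net = diff.empirical_p_and_fdr(t_obs, null, q_star=config.q_star)
        record(
            stage,
            _io.write_difference_network(
                net, out / "difference.tsv", out / "difference_manifest.json"
            ),
        )
        if last == 2:
            return finish()

        stage = "topology"
        for direction, label in (("positive", ga), ("negative", gb)):
            metrics = topo.node_strength(net.t, direction=direction)
            grad = topo.gradient_scan(
                nodes["y_mm"].to_numpy(),
                metrics["strength"].to_numpy(),
                range(config.bins_min, config.bins_max + 1),
            )
            mod = topo.module_metrics(net.t, nodes["tag"].to_numpy(), direction=direction)
            mod["hub_class"] = topo.classify_hubs(
                mod,
                degree_threshold=config.hub_degree_threshold,
                participation_range=(
                    config.hub_participation_min,
                    config.hub_participation_max,
                ),
            )
            merged = metrics.merge(
                mod[
                    ["node_id", "within_module_degree_z", "participation", "hub_class"]
                ],
                on="node_id",
            )
            record(stage, _io.write_node_table(merged, out / f"metrics_{label}.tsv"))
            grad_frame = pd.DataFrame(
                {
                    "n_bins": [g.n_bins for g in grad],
                    "rho": [g.rho for g in grad],
                    "p": [g.p_value for g in grad],
                }
            )
            record(stage, _io.write_node_table(grad_frame, out / f"gradient_{label}.tsv"))
        if last == 3:
            return finish()

        stage = "behavior"
        table = sim.generate_behavior(
            panel,
            truth,
            coeffs=config.behavior_coeffs,
            noise_sd=config.behavior_noise_sd,
            seed=stage_seeds["behavior"],
            measure_corr=config.measure_corr,
        )
        comp = bhv.composite_score(
            table["famous_faces_pct"].to_numpy(), table["cfmt_pct"].to_numpy()
        )
        table["composite"] = comp.scores
        record(stage, _io.write_node_table(table, out / "behavior.tsv"))
        groups = panel.group_names()
        codes = np.array([groups.index(g) for g in panel.groups], dtype=float)
        reg = bhv.edge_behavior_regression(
            comp.scores, codes, table["edge_value"].to_numpy()
        )
        reg_path = out / "behavior_regression.json"
        reg_path.write_text(
            json.dumps(
                {
                    "params": reg.params,
                    "bse": reg.bse,
                    "pvalues": reg.pvalues,
                    "r_squared": reg.r_squared,
                    "r_squared_adj": reg.r_squared_adj,
                    "f_statistic": reg.f_statistic,
                    "variance_explained_pc1": comp.variance_explained,
                },
                indent=2,
            )
        )
        record(stage, reg_path)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return finish()
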