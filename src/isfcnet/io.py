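"""On-disk formats: TSV panels with JSON sidecars, edge matrices, node
tables, difference networks, YAML configs and optional NIfTI volumes.

Panels are stored one wide TSV per subject (rows = timepoints, columns =
nodes) next to a JSON sidecar holding subject id, group and TR.  Edge
matrices round-trip both as square TSV (node-id header) and as long-format
edge lists with each undirected edge stored once (node_i < node_j).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import EdgeMatrix, TimeSeriesPanel
from .difference import DifferenceNetwork

__all__ = [
    "PanelFormatError",
    "write_panel",
    "load_panel",
    "write_edge_matrix",
    "load_edge_matrix",
    "edge_matrix_to_long",
    "write_node_table",
    "load_node_table",
    "write_difference_network",
    "write_volume_nifti",
    "save_yaml",
    "load_yaml",
]


class PanelFormatError(ValueError):
    """A panel directory violates the panel format contract."""


def _node_columns(n: int) -> list[str]:
    return [f"n{i:04d}" for i in range(n)]


def write_panel(panel: TimeSeriesPanel, directory: str | Path) -> Path:
    """Write one TSV + JSON sidecar per subject into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cols = _node_columns(panel.n_nodes)
    for s, sid in enumerate(panel.subject_ids):
        frame = pd.DataFrame(panel.data[s].T, columns=cols)
        frame.to_csv(directory / f"{sid}.tsv", sep="\t", index=False, float_format="%.10g")
        sidecar = {
            "subject_id": sid,
            "group": panel.groups[s],
            "tr_s": panel.tr_s,
            "n_nodes": panel.n_nodes,
            "n_timepoints": panel.n_timepoints,
        }
        (directory / f"{sid}.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def load_panel(directory: str | Path) -> TimeSeriesPanel:
    """Load a panel directory written by :func:`write_panel`, validating
    shapes and sidecar metadata; errors name the offending subject file."""
    directory = Path(directory)
    sidecars = sorted(directory.glob("*.json"))
    if not sidecars:
        raise PanelFormatError(f"no subject sidecars (*.json) found in {directory}")
    data, ids, groups = [], [], []
    tr_s: float | None = None
    shape: tuple[int, int] | None = None
    for sc in sidecars:
        meta = json.loads(sc.read_text())
        for key in ("subject_id", "group", "tr_s"):
            if key not in meta:
                raise PanelFormatError(f"{sc.name}: missing sidecar field {key!r}")
        tsv = sc.with_suffix(".tsv")
        if not tsv.exists():
            raise PanelFormatError(f"{sc.name}: missing series file {tsv.name}")
        frame = pd.read_csv(tsv, sep="\t")
        series = frame.to_numpy(dtype=float).T  # (nodes, timepoints)
        if shape is None:
            shape = series.shape
        elif series.shape != shape:
            raise PanelFormatError(
                f"subject {meta['subject_id']}: series shape {series.shape} "
                f"does not match {shape}"
            )
        expect = (meta.get("n_nodes"), meta.get("n_timepoints"))
        if expect != (None, None) and expect != series.shape:
            raise PanelFormatError(
                f"subject {meta['subject_id']}: sidecar declares {expect}, file has {series.shape}"
            )
        if tr_s is None:
            tr_s = float(meta["tr_s"])
        elif float(meta["tr_s"]) != tr_s:
            raise PanelFormatError(f"subject {meta['subject_id']}: inconsistent TR")
        data.append(series)
        ids.append(meta["subject_id"])
        groups.append(meta["group"])
    return TimeSeriesPanel(
        data=np.stack(data), subject_ids=ids, groups=groups, tr_s=tr_s
    )


# ---------------------------------------------------------------------------
# edge matrices
# ---------------------------------------------------------------------------

def write_edge_matrix(mat: EdgeMatrix, path: str | Path) -> Path:
    path = Path(path)
    cols = _node_columns(mat.n_nodes)
    pd.DataFrame(mat.values, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )
    return path


def load_edge_matrix(path: str | Path, kind: str = "fc") -> EdgeMatrix:
    values = pd.read_csv(path, sep="\t").to_numpy(dtype=float)
    return EdgeMatrix(values=values, kind=kind, symmetric=bool(np.allclose(values, values.T)))


def edge_matrix_to_long(mat: EdgeMatrix) -> pd.DataFrame:
    iu = np.triu_indices(mat.n_nodes, k=1)
    return pd.DataFrame({"node_i": iu[0], "node_j": iu[1], "z": mat.values[iu]})


# ---------------------------------------------------------------------------
# node tables, difference networks
# ---------------------------------------------------------------------------

def write_node_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def load_node_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_difference_network(
    net: DifferenceNetwork, path: str | Path, manifest_path: str | Path | None = None
) -> Path:
    """Long-format TSV of the contrast plus a JSON run manifest."""
    path = Path(path)
    net.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    if manifest_path is not None:
        manifest = {
            "n_perm": net.n_perm,
            "seed": net.seed,
            "q_star": net.q_star,
            "mode": net.mode,
            "n_nodes": net.n_nodes,
        }
        Path(manifest_path).write_text(json.dumps(manifest, indent=2))
    return path


def write_volume_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Save a (3D or 4D) array as NIfTI-1."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))
    return Path(path)


# ---------------------------------------------------------------------------
# YAML config round-trip
# ---------------------------------------------------------------------------

def save_yaml(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(obj, sort_keys=True))
    return path


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
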