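"""Node definition from voxel time series.

Voxels correlated with a face-selective seed and with a non-face-selective
seed (Pearson r at or above a threshold, conventionally 0.5) are unioned
into one mask, each voxel keeping a functional tag (seed-1-only,
seed-2-only, or both).  The masked voxel time courses are then agglomerated
by Ward's variance-minimizing criterion under a spatial-adjacency
constraint so that every parcel is a contiguous cluster; small parcels are
eliminated and each surviving node is tagged by the modal tag of its
voxels.  Node centers are reported in MNI millimeters via the volume
affine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import AgglomerativeClustering

__all__ = [
    "VoxelVolume",
    "NodeTable",
    "seed_correlation_mask",
    "union_and_tag",
    "grid_adjacency",
    "contiguous_ward",
    "tag_and_filter",
    "TAG_SEED1",
    "TAG_SEED2",
    "TAG_BOTH",
]

TAG_SEED1 = 1  # correlated with seed 1 only (face-selective origin)
TAG_SEED2 = 2  # correlated with seed 2 only (non-face origin)
TAG_BOTH = 3   # correlated with both seeds

#: node-level tag names keyed by modal voxel tag
NODE_TAG = {TAG_SEED1: "face", TAG_SEED2: "nonface", TAG_BOTH: "mixed"}

_NEIGHBOR_OFFSETS = {
    6: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    18: [(1, 0, 0), (0, 1, 0), (0, 0, 1),
         (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1)],
    26: [(1, 0, 0), (0, 1, 0), (0, 0, 1),
         (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
         (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)],
}


@dataclass
class VoxelVolume:
    """Voxel time series on a 3D grid with a mask and a grid->MNI affine."""

    data: np.ndarray           # (X, Y, Z, T)
    mask: np.ndarray           # (X, Y, Z) bool, e.g. gray matter
    affine: np.ndarray         # 4x4, grid index -> MNI mm
    voxel_tags: np.ndarray | None = None  # (X, Y, Z) int, 0 outside union

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("volume data must be 4D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match volume grid")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")


@dataclass
class NodeTable:
    """Nodes (parcels) with centers in MNI mm, sizes, tags and voxel lists."""

    frame: pd.DataFrame                      # node_id, x_mm, y_mm, z_mm, voxel_count, tag
    voxels: dict[int, np.ndarray]            # node_id -> (n_vox, 3) grid indices
    dropped_voxel_count: int = 0

    def __post_init__(self) -> None:
        required = {"node_id", "x_mm", "y_mm", "z_mm", "voxel_count", "tag"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"node table missing columns: {sorted(missing)}")
        bad = set(self.frame["tag"]) - set(NODE_TAG.values())
        if bad:
            raise ValueError(f"unknown node tags: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# seed correlation and union
# ---------------------------------------------------------------------------

def seed_correlation_mask(
    volume: VoxelVolume, seed_signal: np.ndarray, r_threshold: float = 0.5
) -> np.ndarray:
    """Binary voxel mask: Pearson r with the seed signal >= r_threshold.

    Only voxels inside the volume's gray-matter mask are eligible.  A voxel
    exactly at the threshold is included.
    """
    seed = np.asarray(seed_signal, dtype=float)
    if seed.ndim != 1 or seed.size != volume.data.shape[3]:
        raise ValueError("seed signal length must equal the voxel series length")
    if seed.std() <= 0:
        raise ValueError("seed signal has zero variance")
    series = volume.data[volume.mask]                     # (n_vox, T)
    zs = series - series.mean(axis=1, keepdims=True)
    sd = zs.std(axis=1)
    sd = np.where(sd > 0, sd, np.inf)                     # zero-variance voxels -> r = 0
    zseed = (seed - seed.mean()) / seed.std()
    r = (zs / sd[:, None]) @ zseed / seed.size
    out = np.zeros(volume.mask.shape, dtype=bool)
    out[volume.mask] = r >= r_threshold
    return out


def union_and_tag(mask1: np.ndarray, mask2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of two seed masks with per-voxel provenance tags.

    Returns ``(union_mask, tags)`` where tags is 0 outside the union and
    TAG_SEED1 / TAG_SEED2 / TAG_BOTH inside.
    """
    if mask1.shape != mask2.shape:
        raise ValueError("seed masks are on different grids")
    union = mask1 | mask2
    tags = np.zeros(mask1.shape, dtype=int)
    tags[mask1 & ~mask2] = TAG_SEED1
    tags[mask2 & ~mask1] = TAG_SEED2
    tags[mask1 & mask2] = TAG_BOTH
    return union, tags


# ---------------------------------------------------------------------------
# spatially constrained Ward clustering
# ---------------------------------------------------------------------------

def grid_adjacency(mask: np.ndarray, connectivity: int = 6) -> coo_matrix:
    """Sparse adjacency among masked voxels under 6/18/26-neighborhood."""
    if connectivity not in _NEIGHBOR_OFFSETS:
        raise ValueError("connectivity must be 6, 18 or 26")
    coords = np.argwhere(mask)
    index = -np.ones(mask.shape, dtype=int)
    index[tuple(coords.T)] = np.arange(len(coords))
    rows, cols = [], []
    for off in _NEIGHBOR_OFFSETS[connectivity]:
        nb = coords + np.array(off)
        ok = np.all((nb >= 0) & (nb < np.array(mask.shape)), axis=1)
        src = index[tuple(coords[ok].T)]
        dst = index[tuple(nb[ok].T)]
        hit = dst >= 0
        rows.extend(src[hit])
        cols.extend(dst[hit])
    n = len(coords)
    data = np.ones(2 * len(rows))
    adj = coo_matrix(
        (data, (np.r_[rows, cols], np.r_[cols, rows])), shape=(n, n)
    )
    adj.sum_duplicates()
    adj.data[:] = 1.0
    return adj


def contiguous_ward(
    voxel_series: np.ndarray,
    mask: np.ndarray,
    max_clusters: int,
    *,
    connectivity: int = 6,
) -> np.ndarray:
    """Spatially constrained Ward agglomeration of masked voxel time courses.

    Merges are allowed only between spatially adjacent clusters, so every
    parcel is contiguous.  Disconnected mask components are clustered
    separately, with the cluster budget split across components in
    proportion to their size (each component receives at least one).
    Returns a full-grid integer label array (-1 outside the mask).

    ``voxel_series`` is either the 4D volume array or an (n_masked, T)
    matrix aligned with ``np.argwhere(mask)`` order.
    """
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("empty mask")
    if not 1 <= max_clusters <= n_vox:
        raise ValueError("max_clusters must lie in [1, number of masked voxels]")
    X = np.asarray(voxel_series, dtype=float)
    if X.ndim == 4:
        X = X[mask]
    if X.shape[0] != n_vox:
        raise ValueError("voxel series do not align with the mask")

    adj = grid_adjacency(mask, connectivity).tocsr()
    n_comp, comp = connected_components(adj, directed=False)

    # allocate cluster counts per connected component (largest remainder)
    sizes = np.bincount(comp, minlength=n_comp)
    if max_clusters < n_comp:
        raise ValueError(
            f"mask has {n_comp} disconnected components; max_clusters must be >= {n_comp}"
        )
    quota = np.ones(n_comp, dtype=int)
    remaining = max_clusters - n_comp
    if remaining > 0:
        frac = sizes / sizes.sum() * remaining
        quota += np.floor(frac).astype(int)
        short = remaining - int(np.floor(frac).sum())
        for idx in np.argsort(-(frac - np.floor(frac)), kind="stable")[:short]:
            quota[idx] += 1
    quota = np.minimum(quota, sizes)  # cannot exceed voxels in a component

    labels_flat = -np.ones(n_vox, dtype=int)
    next_label = 0
    for c in range(n_comp):
        members = np.where(comp == c)[0]
        k = int(quota[c])
        if k >= len(members):
            labels_flat[members] = next_label + np.arange(len(members))
            next_label += len(members)
            continue
        if k == 1:
            labels_flat[members] = next_label
            next_label += 1
            continue
        sub_adj = adj[members][:, members]
        model = AgglomerativeClustering(
            n_clusters=k, linkage="ward", connectivity=sub_adj
        )
        sub_labels = model.fit_predict(X[members])
        labels_flat[members] = next_label + sub_labels
        next_label += k

    out = -np.ones(mask.shape, dtype=int)
    out[mask] = labels_flat
    return out


# ---------------------------------------------------------------------------
# tagging and size filtering
# ---------------------------------------------------------------------------

def tag_and_filter(
    labels: np.ndarray,
    voxel_tags: np.ndarray,
    affine: np.ndarray,
    min_size: int = 10,
) -> NodeTable:
    """Build the node table: drop small clusters, tag the rest by modal vote.

    Clusters with fewer than ``min_size`` voxels are eliminated.  The node
    tag is the modal voxel tag (face / nonface / mixed); an exact tie is
    resolved conservatively to "mixed".  Node centers are the mean MNI-mm
    coordinates of the constituent voxels.
    """
    if labels.shape != voxel_tags.shape:
        raise ValueError("labels and voxel tags are on different grids")
    rows, voxmap = [], {}
    dropped = 0
    node_id = 0
    for lab in np.unique(labels[labels >= 0]):
        coords = np.argwhere(labels == lab)
        if len(coords) < min_size:
            dropped += len(coords)
            continue
        tags = voxel_tags[tuple(coords.T)]
        counts = {t: int((tags == t).sum()) for t in (TAG_SEED1, TAG_SEED2, TAG_BOTH)}
        best = max(counts.values())
        winners = [t for t, c in counts.items() if c == best]
        tag = NODE_TAG[winners[0]] if len(winners) == 1 else "mixed"
        mm = (affine @ np.c_[coords, np.ones(len(coords))].T)[:3].mean(axis=1)
        rows.append(
            {
                "node_id": node_id,
                "x_mm": mm[0],
                "y_mm": mm[1],
                "z_mm": mm[2],
                "voxel_count": len(coords),
                "tag": tag,
            }
        )
        voxmap[node_id] = coords
        node_id += 1
    if not rows:
        raise ValueError("no clusters survive the size filter")
    return NodeTable(
        frame=pd.DataFrame(rows), voxels=voxmap, dropped_voxel_count=dropped
    )
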