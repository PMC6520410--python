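"""Iterative contiguity-refined hierarchical clustering of z-slices.

Each iteration ward-clusters the per-slice feature rows (Euclidean
distance) with a maximum cluster budget MC, splits every cluster into its
maximal contiguous runs of slices ("c-layers"), replaces each slice's
features by the mean of the original features over its c-layer, then
decrements MC.  Iterating from MC0 down to 1 yields a nested hierarchy:
because slices of one c-layer carry identical (averaged) features, later
cuts can never split them, so each level coarsens the previous one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage

from .model_io import CLayer, HierarchyLevel, Labeling, LayerHierarchy

__all__ = [
    "ClusteringParams",
    "cluster_once",
    "refine_to_clayers",
    "average_features_by_clayer",
    "build_hierarchy",
    "get_level_labeling",
]


@dataclass
class ClusteringParams:
    """mc0 is the cluster budget of the first iteration; linkage and
    metric are fixed to ward/Euclidean."""

    mc0: int = 10

    def __post_init__(self) -> None:
        if self.mc0 < 2:
            raise ValueError("mc0 must be at least 2")


def cluster_once(features: np.ndarray, mc: int) -> np.ndarray:
    """Ward-linkage clustering of feature rows, cut to min(mc, #distinct rows).

    Identical rows always land in the same cluster (they are deduplicated
    before linkage), which is what makes the iterated hierarchy nested.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.ndim != 2:
        raise ValueError("features must be a 2D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    if mc < 1:
        raise ValueError("mc must be >= 1")
    n = X.shape[0]
    uniq, inverse = np.unique(X, axis=0, return_inverse=True)
    k = min(mc, uniq.shape[0])
    if k == 1 or uniq.shape[0] == 1:
        return np.zeros(n, dtype=int)
    Z = linkage(uniq, method="ward")
    cut = cut_tree(Z, n_clusters=k).ravel()
    return cut[inverse].astype(int)


def refine_to_clayers(cluster_ids: np.ndarray) -> list[tuple[int, int, int]]:
    """Split clusters into maximal contiguous slice runs.

    Returns (z_start, z_end, cluster_id) triples ordered superficial to
    deep; every isolated part of a cluster becomes its own c-layer.
    """
    ids = np.asarray(cluster_ids).ravel()
    if ids.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(ids)) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [ids.size]])
    return [(int(s), int(e), int(ids[s])) for s, e in zip(starts, ends)]


def average_features_by_clayer(
    features: np.ndarray, clayers: list[tuple[int, int, int]]
) -> np.ndarray:
    """Replace every row by the mean over its c-layer's rows."""
    X = np.asarray(features, dtype=float)
    out = np.empty_like(X)
    for s, e, _ in clayers:
        out[s:e] = X[s:e].mean(axis=0)
    return out


def build_hierarchy(
    features: np.ndarray, params: ClusteringParams | None = None
) -> LayerHierarchy:
    """Run the full iterative clustering, MC = mc0 down to 1.

    Feature averaging at each level recomputes means of the *original*
    features over the new c-layers, so every level's rows are exact means
    of raw per-slice data regardless of c-layer sizes.
    """
    params = params or ClusteringParams()
    raw = np.asarray(features, dtype=float)
    if raw.ndim == 1:
        raw = raw.reshape(-1, 1)
    z_max = raw.shape[0]
    if z_max < 2:
        raise ValueError("need at least 2 slices to build a hierarchy")
    levels: list[HierarchyLevel] = []
    current = raw
    for mc in range(params.mc0, 0, -1):
        ids = cluster_once(current, mc)
        runs = refine_to_clayers(ids)
        clayers = tuple(
            CLayer(s, e, cid, idx)
            for idx, (s, e, cid) in enumerate(runs, start=1)
        )
        levels.append(HierarchyLevel(mc=mc, clayers=clayers))
        current = average_features_by_clayer(raw, runs)
    return LayerHierarchy(z_max=z_max, levels=levels)


def get_level_labeling(h: LayerHierarchy, level: int) -> Labeling:
    """Slice labeling by c-layer index at a 1-based hierarchy level."""
    labels = h.slice_labels(level)
    return Labeling([str(v) for v in labels], label_set_name=f"c-layers L{level}")
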