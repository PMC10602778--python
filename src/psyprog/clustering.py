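"""Patient subtyping by Ward clustering of importance maps.

Agglomerative hierarchical clustering (Ward criterion, Euclidean distance
on the raw probability-scale maps) of the per-patient 48-item importance
maps; the headline cut is k = 2, and the cluster whose mean map has the
smaller L1 norm is reported as the "limited-effect" subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray         # scipy flat linkage (merges + heights)
    labels: np.ndarray                 # cluster id (0-based) per patient
    k: int
    mean_maps: np.ndarray              # (k, n_items)
    cluster_sizes: np.ndarray          # (k,)


def ward_cluster(maps_matrix: np.ndarray, k: int = 2) -> ClusterResult:
    """Ward linkage on Euclidean distances, cut at ``k`` clusters.

    Cluster ids are relabeled by order of first appearance in the input,
    so the labeling is deterministic given row order.
    """
    X = np.asarray(maps_matrix, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if n == 1:
        return ClusterResult(np.empty((0, 4)), np.zeros(1, dtype=int), 1,
                             X.copy(), np.array([1]))
    Z = linkage(X, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel by first appearance for determinism
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        labels[i] = remap[r]
    k_eff = len(remap)
    means = cluster_mean_maps(X, labels)
    sizes = np.bincount(labels, minlength=k_eff)
    return ClusterResult(Z, labels, k_eff, means, sizes)


def cluster_mean_maps(maps_matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Arithmetic mean map per cluster, item order preserved."""
    X = np.asarray(maps_matrix, dtype=float)
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if not np.array_equal(ids, np.arange(len(ids))):
        raise ValueError("labels must be 0..k-1")
    return np.vstack([X[labels == c].mean(axis=0) for c in ids])


def near_zero_cluster_report(result: ClusterResult) -> dict:
    """Identify the limited-effect cluster of a two-cluster solution.

    The cluster whose mean map has the smaller L1 norm is the
    "limited-effect" subgroup (predictions barely moved by comorbidity
    flips); ties break toward the lower cluster id and are flagged.
    """
    if result.k != 2:
        raise ValueError(f"expected a 2-cluster result, got k={result.k}")
    norms = np.abs(result.mean_maps).sum(axis=1)
    tie = bool(np.isclose(norms[0], norms[1]))
    limited = 0 if tie else int(np.argmin(norms))
    n = int(result.cluster_sizes.sum())
    assert all(s > 0 for s in result.cluster_sizes), "cut cannot yield empty clusters"
    return {
        "limited_effect_cluster": limited,
        "l1_norms": [float(x) for x in norms],
        "cluster_sizes": [int(s) for s in result.cluster_sizes],
        "limited_effect_fraction": float(result.cluster_sizes[limited] / n),
        "tie": tie,
    }
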