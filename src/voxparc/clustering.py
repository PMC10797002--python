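"""Unweighted average-linkage (UPGMA) clustering of the distance matrix.

Builds the linkage tree, extracts nested K-cluster solutions, relabels
clusters along a spatial axis and exports dendrograms as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy

from .connectivity import DistanceMatrix


@dataclass
class LinkageTree:
    """Agglomerative merge records in the standard linkage layout.

    ``merges`` has one row per merge: (node_a, node_b, height, size), where
    leaves are 0..n-1 and merge i creates node n+i.
    """

    merges: np.ndarray
    n_leaves: int

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        if self.merges.shape != (self.n_leaves - 1, 4):
            raise ValueError(
                f"expected {self.n_leaves - 1} merge records, got {self.merges.shape}"
            )

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class ClusterSolution:
    """Per-voxel labels for a cut of the linkage tree at K clusters.

    Labels are 1-based; id assignment is deterministic (by lowest member
    index, unless relabelled along an axis).
    """

    k: int
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValueError(f"labels must use every id in 1..{self.k}, got {present}")

    @property
    def n_voxels(self) -> int:
        return self.labels.size

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


def linkage_upgma(d: DistanceMatrix) -> LinkageTree:
    """UPGMA linkage: merge height = unweighted mean of cross-pair distances."""
    merges = hierarchy.linkage(d.condensed(), method="average")
    return LinkageTree(merges=merges, n_leaves=d.n_voxels)


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary label values to 1..k ordered by lowest member index."""
    order: dict = {}
    for v in raw:
        if v not in order:
            order[v] = len(order) + 1
    return np.array([order[v] for v in raw], dtype=int)


def cut_tree(tree: LinkageTree, k: int) -> ClusterSolution:
    """Cut the linkage tree into exactly ``k`` clusters (1-based ids)."""
    if not (1 <= k <= tree.n_leaves):
        raise ValueError(f"k must be in 1..{tree.n_leaves}, got {k}")
    raw = hierarchy.cut_tree(tree.merges, n_clusters=k).ravel()
    labels = _canonical_labels(raw)
    return ClusterSolution(k=k, labels=labels)


def cut_range(tree: LinkageTree, k_range: Sequence[int]) -> dict[int, ClusterSolution]:
    """Nested solutions for every K in ``k_range`` from a single tree."""
    return {k: cut_tree(tree, k) for k in k_range}


def relabel_along_axis(
    sol: ClusterSolution, coords: np.ndarray, axis: int = 0
) -> ClusterSolution:
    """Reorder cluster ids by ascending mean coordinate along ``axis``.

    The partition itself is unchanged; ties in the mean keep the lower
    original id first.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    if coords.shape[0] != sol.n_voxels:
        raise ValueError(
            f"coords has {coords.shape[0]} rows for {sol.n_voxels} voxels"
        )
    if np.any(~np.isfinite(coords[:, axis])):
        raise ValueError("coordinates contain non-finite values")
    means = [(coords[sol.members(c), axis].mean(), c) for c in range(1, sol.k + 1)]
    order = sorted(means)  # (mean, original id): ties keep lower id first
    mapping = {old: new for new, (_, old) in enumerate(order, start=1)}
    return replace(sol, labels=np.array([mapping[v] for v in sol.labels]))


def to_newick(tree: LinkageTree, leaf_names: Optional[Sequence[str]] = None) -> str:
    """Serialize the linkage tree as a Newick string with branch lengths."""
    if leaf_names is None:
        leaf_names = [f"v{i}" for i in range(tree.n_leaves)]
    if len(leaf_names) != tree.n_leaves:
        raise ValueError("one leaf name per leaf required")
    root, _ = hierarchy.to_tree(tree.merges, rd=True)

    def recurse(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id]
        left, right = node.get_left(), node.get_right()
        parts = []
        for child in (left, right):
            length = node.dist - child.dist
            parts.append(f"{recurse(child)}:{length:.6g}")
        return f"({','.join(parts)})"

    return recurse(root) + ";"
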