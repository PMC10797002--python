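"""Cluster-to-brain connectivity maps with fixed-effects group combination."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .clustering import ClusterSolution
from .connectivity import fisher_z


@dataclass
class BrainZMap:
    """Per-voxel Fisher-z map for one source cluster.

    ``excluded`` flags voxels that belong to the source cluster itself;
    their z entries are filled with 0 and must be ignored downstream.
    """

    z: np.ndarray
    excluded: np.ndarray
    source_cluster: int
    n_runs_combined: int
    space: str = "unspecified"
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.z.shape != self.excluded.shape:
            raise ValueError("z and excluded masks must share a shape")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z map must be finite")


def cluster_to_brain(
    brain_data: np.ndarray,
    sol: ClusterSolution,
    cluster_id: int,
) -> BrainZMap:
    """Per-run z map: cluster-mean time course vs every out-of-cluster voxel.

    ``brain_data`` is ``(n_brain_voxels, n_timepoints)``, already band-passed
    and nuisance-regressed; the first ``sol.n_voxels`` rows are the mask
    voxels carrying the cluster labels, anything beyond is extra brain.
    """
    brain_data = np.asarray(brain_data, dtype=float)
    if brain_data.shape[0] < sol.n_voxels:
        raise ValueError("brain data has fewer voxels than the cluster solution")
    members = sol.members(cluster_id)
    if members.size == 0:
        raise ValueError(f"cluster {cluster_id} is empty")
    mean_ts = brain_data[members].mean(axis=0)
    excluded = np.zeros(brain_data.shape[0], dtype=bool)
    excluded[members] = True
    target = brain_data[~excluded]
    mc = mean_ts - mean_ts.mean()
    tc = target - target.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(tc, axis=1) * np.linalg.norm(mc)
    if np.any(denom == 0):
        raise ValueError("zero-variance voxel or cluster time course")
    r = np.clip(tc @ mc / denom, -1.0, 1.0)
    z = np.zeros(brain_data.shape[0])
    z[~excluded] = fisher_z(r)
    return BrainZMap(z=z, excluded=excluded, source_cluster=cluster_id, n_runs_combined=1)


def fixed_effects_combine(
    maps: Sequence[BrainZMap], method: str = "stouffer"
) -> BrainZMap:
    """Combine per-run z maps into one group map.

    ``stouffer`` (default) uses sum(z) / sqrt(N); ``mean`` plain-averages,
    which changes only the scale, not the voxel ranking.
    """
    if not maps:
        raise ValueError("no maps to combine")
    shape = maps[0].z.shape
    cluster = maps[0].source_cluster
    for m in maps:
        if m.z.shape != shape:
            raise ValueError("map grids differ")
        if m.source_cluster != cluster:
            raise ValueError("maps come from different source clusters")
    stack = np.stack([m.z for m in maps])
    n = len(maps)
    if method == "stouffer":
        z = stack.sum(axis=0) / np.sqrt(n)
    elif method == "mean":
        z = stack.mean(axis=0)
    else:
        raise ValueError(f"unknown combination method {method!r}")
    excluded = np.logical_or.reduce([m.excluded for m in maps])
    z[excluded] = 0.0
    return BrainZMap(
        z=z, excluded=excluded, source_cluster=cluster, n_runs_combined=n
    )


def threshold_map(
    zmap: BrainZMap, z_threshold: float = 2.3, background: float = 0.0
) -> tuple[BrainZMap, np.ndarray, int]:
    """Keep voxels with z strictly above the threshold.

    Returns the thresholded map, the binary survivor mask, and the survivor
    count (excluded source-cluster voxels never survive).
    """
    survivors = (zmap.z > z_threshold) & ~zmap.excluded
    z = np.where(survivors, zmap.z, background)
    out = BrainZMap(
        z=z,
        excluded=zmap.excluded,
        source_cluster=zmap.source_cluster,
        n_runs_combined=zmap.n_runs_combined,
        space=zmap.space,
        threshold=z_threshold,
    )
    return out, survivors, int(survivors.sum())
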