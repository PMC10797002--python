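"""Group-level voxel-by-voxel connectivity and profile distances.

Per-run partial correlations (controlling for the nuisance set), Fisher
z-transform, two-stage group averaging (runs within subject, then subjects),
and the Euclidean distance between connectivity profiles that feeds
hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .qc import VoxelTimeSeriesRun, regress_nuisance

#: correlations are clipped to 1 - ATANH_CLIP in magnitude before atanh
ATANH_CLIP = 1e-7


@dataclass
class GroupZMatrix:
    """Voxel-by-voxel Fisher-z connectivity averaged across runs then subjects.

    The diagonal is defined as 0 by convention (the self-correlation z would
    be the clipping cap and carries no information).
    """

    z: np.ndarray
    n_subjects: int
    n_runs_per_subject: dict[str, int]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("z must be square")
        if not np.allclose(self.z, self.z.T):
            raise ValueError("z must be symmetric")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z must be finite")
        if np.any(np.diag(self.z) != 0):
            raise ValueError("diagonal must be exactly 0")

    @property
    def n_voxels(self) -> int:
        return self.z.shape[0]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative Euclidean distances between z-profile rows."""

    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise ValueError("d must be square")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("d must be symmetric")
        if np.any(self.d < 0):
            raise ValueError("d must be nonnegative")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("d must have a zero diagonal")

    @property
    def n_voxels(self) -> int:
        return self.d.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


def run_connectivity(run: VoxelTimeSeriesRun) -> np.ndarray:
    """Voxel-by-voxel partial correlation matrix for one run.

    Pearson correlation of the nuisance-regressed residuals, which equals
    the partial correlation of every voxel pair controlling for the nuisance
    set. The run is expected to be band-passed already.
    """
    resid = regress_nuisance(run)
    sd = resid.std(axis=1)
    # a voxel fully explained by the nuisance set leaves only rounding noise
    floor = 1e-10 * np.maximum(run.data.std(axis=1), np.finfo(float).tiny)
    if np.any(sd <= floor):
        bad = int(np.flatnonzero(sd <= floor)[0])
        raise ValueError(f"voxel {bad} has zero-variance residual")
    c = np.corrcoef(resid)
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def fisher_z(r, clip: float = ATANH_CLIP):
    """Fisher r-to-z transform, atanh with magnitude clipped to ``1 - clip``.

    Accepts scalars or arrays; odd and monotone in r.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("|r| > 1 is not a correlation")
    z = np.arctanh(np.clip(r, -1.0 + clip, 1.0 - clip))
    return float(z) if z.ndim == 0 else z


def average_group(
    per_subject_z: Mapping[str, Sequence[np.ndarray]]
) -> GroupZMatrix:
    """Two-stage average: z-matrices across runs per subject, then subjects.

    Subjects with unequal run counts weigh equally in the group mean. The
    diagonal of the result is forced to 0.
    """
    if not per_subject_z:
        raise ValueError("no subjects given")
    subject_means = []
    run_counts: dict[str, int] = {}
    shape = None
    for subject, mats in per_subject_z.items():
        mats = [np.asarray(m, dtype=float) for m in mats]
        if not mats:
            raise ValueError(f"subject {subject!r} has no runs")
        for m in mats:
            if shape is None:
                shape = m.shape
            if m.shape != shape:
                raise ValueError(
                    f"subject {subject!r}: matrix shape {m.shape} != {shape}"
                )
        subject_means.append(np.mean(mats, axis=0))
        run_counts[str(subject)] = len(mats)
    z = np.mean(subject_means, axis=0)
    z = (z + z.T) / 2.0  # guard against tiny asymmetries
    np.fill_diagonal(z, 0.0)
    return GroupZMatrix(z=z, n_subjects=len(per_subject_z), n_runs_per_subject=run_counts)


def profile_distance(gz: GroupZMatrix) -> DistanceMatrix:
    """Euclidean distance between connectivity-profile rows of the z matrix.

    Row self-entries participate with the 0-diagonal convention.
    """
    if not np.all(np.isfinite(gz.z)):
        raise ValueError("group z matrix contains non-finite entries")
    d = squareform(pdist(gz.z, metric="euclidean"))
    return DistanceMatrix(d=d)
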