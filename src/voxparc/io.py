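"""File formats, seed geometry, configuration and run manifests.

Conventions: NIfTI world coordinates in mm via the affine; voxel indices
0-based; mask voxel ordering is the C-order scan of the mask volume and is
recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .qc import VoxelTimeSeriesRun
from .synthetic import NUISANCE_COLUMNS, GroundTruth, RestDataset, SyntheticConfig


@dataclass
class SeedDefinition:
    """A spherical seed region in template space (mm)."""

    name: str
    center: tuple[float, float, float]
    radius: float = 2.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"seed {self.name!r}: radius must be positive")


def resolve_seed_voxels(
    seed: SeedDefinition, affine: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    """Voxel (i, j, k) indices whose center lies within the seed sphere.

    Distances are Euclidean in world mm through the grid affine; indices are
    0-based. Raises when the sphere covers no voxel center.
    """
    affine = np.asarray(affine, dtype=float)
    center = np.asarray(seed.center, dtype=float)
    # invert once; search only the bounding box around the center
    inv = np.linalg.inv(affine)
    c_vox = (inv @ np.append(center, 1.0))[:3]
    # conservative half-width in voxels along each axis
    scales = np.linalg.norm(affine[:3, :3], axis=0)
    half = np.ceil(seed.radius / scales).astype(int) + 1
    lo = np.maximum(np.floor(c_vox).astype(int) - half, 0)
    hi = np.minimum(np.ceil(c_vox).astype(int) + half + 1, np.asarray(shape))
    if np.any(lo >= hi):
        raise ValueError(f"seed {seed.name!r} lies outside the grid")
    ii, jj, kk = np.meshgrid(
        *[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij"
    )
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    world = (affine @ np.column_stack([ijk, np.ones(len(ijk))]).T).T[:, :3]
    inside = np.linalg.norm(world - center, axis=1) <= seed.radius
    if not inside.any():
        raise ValueError(f"seed {seed.name!r} covers no voxel center")
    return ijk[inside]


@dataclass
class PipelineConfig:
    """Every analysis constant, defaulting to the published values."""

    band_low_hz: float = 0.0025
    band_high_hz: float = 0.05
    filter_order: int = 4
    fixation_threshold: float = 0.85
    mean_correlation_statistic: str = "pairwise"
    k_min: int = 2
    k_max: int = 10
    n_perm: int = 100_000
    alpha: float = 0.05
    z_threshold: float = 2.3
    seed_radius_mm: float = 2.0
    hrf_kind: str = "mion"
    fixed_effects: str = "stouffer"
    rng_seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError("need 2 <= k_min <= k_max")

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn_raw = raw.pop("synthetic", {})
        if "seed_mixing" in syn_raw and syn_raw["seed_mixing"] is not None:
            syn_raw["seed_mixing"] = np.asarray(syn_raw["seed_mixing"], dtype=float)
        return cls(synthetic=SyntheticConfig(**syn_raw), **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"]["seed_mixing"] = self.synthetic.seed_mixing.tolist()
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# dataset persistence


def _default_affine() -> np.ndarray:
    return np.eye(4)


def write_rest_dataset(dataset: RestDataset, outdir: str | Path) -> Path:
    """Write runs as 4D NIfTI + TSV nuisance/seeds, truth map and manifest.

    The synthetic voxel ordering maps onto a (n_voxels, 1, 1) grid so the
    C-order scan of the mask reproduces the analysis ordering exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = _default_affine()
    n_vox = dataset.truth.labels.size
    mask_img = nib.Nifti1Image(
        np.ones((n_vox, 1, 1), dtype=np.int16), affine
    )
    nib.save(mask_img, outdir / "mask.nii")
    truth_img = nib.Nifti1Image(
        dataset.truth.labels.reshape(n_vox, 1, 1).astype(np.int16), affine
    )
    nib.save(truth_img, outdir / "truth_labels.nii")
    np.savetxt(
        outdir / "seed_mixing.tsv", dataset.truth.seed_mixing, delimiter="\t"
    )
    entries = []
    for run, seed_ts in zip(dataset.runs, dataset.seeds):
        stem = run.run_id
        img = nib.Nifti1Image(
            run.data.reshape(n_vox, 1, 1, run.n_timepoints).astype(np.float64), affine
        )
        img.header.set_zooms((1.0, 1.0, 1.0, run.tr_seconds))
        nib.save(img, outdir / f"{stem}.nii")
        pd.DataFrame(run.nuisance, columns=NUISANCE_COLUMNS[: run.nuisance.shape[1]]).to_csv(
            outdir / f"{stem}_nuisance.tsv", sep="\t", index=False
        )
        np.savetxt(outdir / f"{stem}_seeds.tsv", seed_ts, delimiter="\t")
        entries.append(
            {
                "run_id": run.run_id,
                "subject_id": run.subject_id,
                "tr_seconds": run.tr_seconds,
                "fixation_fraction": run.fixation_fraction,
                "data": f"{stem}.nii",
                "nuisance": f"{stem}_nuisance.tsv",
                "seeds": f"{stem}_seeds.tsv",
            }
        )
    manifest = {
        "voxel_ordering": "C-order scan of mask.nii",
        "n_voxels": int(n_vox),
        "runs": entries,
        "truth_labels": "truth_labels.nii",
        "seed_mixing": "seed_mixing.tsv",
    }
    write_manifest(outdir / "manifest.json", manifest, checksum_dir=outdir)
    return outdir


def load_rest_dataset(datadir: str | Path) -> RestDataset:
    datadir = Path(datadir)
    manifest = json.loads((datadir / "manifest.json").read_text())
    truth_img = nib.load(datadir / manifest["truth_labels"])
    labels = np.asarray(truth_img.dataobj).ravel(order="C").astype(int)
    mixing = np.loadtxt(datadir / manifest["seed_mixing"], delimiter="\t")
    truth = GroundTruth(labels=labels, seed_mixing=np.atleast_2d(mixing))
    runs, seeds = [], []
    for entry in manifest["runs"]:
        img = nib.load(datadir / entry["data"])
        arr = np.asarray(img.dataobj)
        data = arr.reshape(-1, arr.shape[-1], order="C")
        nuisance = pd.read_csv(datadir / entry["nuisance"], sep="\t").to_numpy()
        runs.append(
            VoxelTimeSeriesRun(
                data=data,
                nuisance=nuisance,
                tr_seconds=float(entry["tr_seconds"]),
                subject_id=entry["subject_id"],
                run_id=entry["run_id"],
                fixation_fraction=entry["fixation_fraction"],
            )
        )
        seeds.append(np.atleast_2d(np.loadtxt(datadir / entry["seeds"], delimiter="\t")))
    return RestDataset(runs=runs, seeds=seeds, truth=truth)


def write_labels_nifti(
    labels: np.ndarray, path: str | Path, affine: Optional[np.ndarray] = None
) -> None:
    """Integer label map on the (n_voxels, 1, 1) synthetic grid."""
    if affine is None:
        affine = _default_affine()
    labels = np.asarray(labels, dtype=np.int16)
    img = nib.Nifti1Image(labels.reshape(-1, 1, 1), affine)
    nib.save(img, str(path))


def read_labels_nifti(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj).ravel(order="C").astype(int)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path, payload: dict, checksum_dir: Optional[str | Path] = None
) -> None:
    """JSON manifest; optionally append sha256 checksums of sibling files."""
    payload = dict(payload)
    if checksum_dir is not None:
        checksums = {}
        for f in sorted(Path(checksum_dir).iterdir()):
            if f.is_file() and f.name != Path(path).name:
                checksums[f.name] = file_sha256(f)
        payload["checksums"] = checksums
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def exclusion_log_to_csv(log, path: str | Path) -> None:
    records = log.as_records()
    df = pd.DataFrame(records, columns=["run_id", "subject_id", "reason", "value"])
    df.to_csv(path, index=False)
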