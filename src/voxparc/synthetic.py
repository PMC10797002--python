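"""Synthetic multi-subject, multi-run voxel time series with known structure.

Generates everything the analysis pipeline consumes: resting runs with K
latent communities sharing band-limited signals, external seed series with
configurable community coupling, additive nuisance (white matter,
ventricle, motion) series, null fingerprint pairs for permutation-test
calibration, and block-design task runs with planted percent-signal-change
effects. All randomness flows from a single seed; identical configurations
reproduce bit-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .qc import VoxelTimeSeriesRun
from .task import BlockDesign, hrf_regressors, regressor_peak
from .validation import Fingerprint

#: nuisance layout: white-matter mean, ventricle mean, six motion parameters
NUISANCE_COLUMNS = ["wm", "csf", "tx", "ty", "tz", "rx", "ry", "rz"]

_SEED_NOISE_SD = 0.5
_AR1_PHI = 0.9


@dataclass
class SyntheticConfig:
    """Parameters of the planted-community resting-state generator."""

    n_voxels: int = 80
    k_true: int = 4
    n_seeds: int = 23
    n_subjects: int = 8
    n_runs_per_subject: int = 3
    n_volumes: int = 300
    tr_seconds: float = 2.0
    community_snr: float = 2.0  # latent-signal sd / noise sd (inf = noise-free)
    seed_mixing: Optional[np.ndarray] = None  # (k_true, n_seeds) nonnegative
    nuisance_amplitude: float = 0.5
    band: tuple[float, float] = (0.0025, 0.05)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_voxels",
            "k_true",
            "n_seeds",
            "n_subjects",
            "n_runs_per_subject",
            "n_volumes",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.k_true > self.n_voxels:
            raise ValueError("k_true cannot exceed n_voxels")
        if self.community_snr < 0 or self.nuisance_amplitude < 0:
            raise ValueError("ratios must be nonnegative")
        if self.seed_mixing is None:
            self.seed_mixing = default_seed_mixing(self.k_true, self.n_seeds)
        self.seed_mixing = np.asarray(self.seed_mixing, dtype=float)
        if self.seed_mixing.shape != (self.k_true, self.n_seeds):
            raise ValueError(
                f"seed_mixing must be ({self.k_true}, {self.n_seeds}), "
                f"got {self.seed_mixing.shape}"
            )
        if np.any(self.seed_mixing < 0):
            raise ValueError("seed_mixing must be nonnegative")


def default_seed_mixing(k_true: int, n_seeds: int) -> np.ndarray:
    """Distinct rows: each community couples strongly to its own seed subset."""
    s = np.arange(n_seeds)
    c = np.arange(k_true)[:, None]
    return 0.2 + 0.8 * (s[None, :] % k_true == c)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks downstream."""

    labels: np.ndarray  # per-voxel community id in 1..k_true
    seed_mixing: np.ndarray
    planted_effects: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        k = self.seed_mixing.shape[0]
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, k + 1)):
            raise ValueError("every community id in 1..k_true must appear")

    @property
    def k_true(self) -> int:
        return self.seed_mixing.shape[0]


@dataclass
class RestDataset:
    runs: list[VoxelTimeSeriesRun]
    seeds: list[np.ndarray]  # aligned with runs, (n_seeds, n_volumes) each
    truth: GroundTruth

    def runs_by_subject(self) -> dict[str, list[VoxelTimeSeriesRun]]:
        out: dict[str, list[VoxelTimeSeriesRun]] = {}
        for run in self.runs:
            out.setdefault(run.subject_id, []).append(run)
        return out


def band_limited_signals(
    rng: np.random.Generator,
    n_signals: int,
    n_volumes: int,
    tr_seconds: float,
    band: tuple[float, float],
) -> np.ndarray:
    """Unit-variance Gaussian signals with support restricted to the band.

    Built in the frequency domain so the band-pass stage of the pipeline is
    approximately structure-preserving.
    """
    freqs = np.fft.rfftfreq(n_volumes, tr_seconds)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError("band contains no resolvable frequency")
    coef = np.zeros((n_signals, freqs.size), dtype=complex)
    n_in = int(in_band.sum())
    coef[:, in_band] = rng.standard_normal((n_signals, n_in)) + 1j * rng.standard_normal(
        (n_signals, n_in)
    )
    x = np.fft.irfft(coef, n=n_volumes, axis=1)
    sd = x.std(axis=1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def ar1_series(
    rng: np.random.Generator, n_series: int, n_volumes: int, phi: float = _AR1_PHI
) -> np.ndarray:
    """Stationary unit-variance Gaussian AR(1) processes (smooth nuisance)."""
    innov_sd = np.sqrt(1.0 - phi**2)
    x = np.empty((n_series, n_volumes))
    x[:, 0] = rng.standard_normal(n_series)
    eps = rng.standard_normal((n_series, n_volumes - 1)) * innov_sd
    for t in range(1, n_volumes):
        x[:, t] = phi * x[:, t - 1] + eps[:, t - 1]
    return x


def community_labels(n_voxels: int, k_true: int) -> np.ndarray:
    """Contiguous 1-based community blocks along the voxel ordering."""
    base = np.repeat(np.arange(1, k_true + 1), n_voxels // k_true)
    return np.concatenate([base, np.full(n_voxels - base.size, k_true)])


def generate_rest_dataset(config: SyntheticConfig) -> RestDataset:
    """Resting runs with planted communities, seeds and nuisance series.

    Each community carries one band-limited latent per run; voxel v in
    community c emits ``snr * L_c + nuisance_amplitude * (w . nuisance) +
    noise``; seed s emits ``sum_c mixing[c, s] * L_c + noise``. With
    ``community_snr = inf`` both noise terms vanish (amplitude 1 latents).
    """
    rng = np.random.default_rng(config.rng_seed)
    labels = community_labels(config.n_voxels, config.k_true)
    truth = GroundTruth(labels=labels, seed_mixing=config.seed_mixing)
    noise_free = np.isinf(config.community_snr)
    amp = 1.0 if noise_free else config.community_snr
    # fixed per-voxel nuisance loadings shared across runs
    loadings = rng.uniform(0.5, 1.5, size=(config.n_voxels, len(NUISANCE_COLUMNS)))
    runs: list[VoxelTimeSeriesRun] = []
    seeds: list[np.ndarray] = []
    for s in range(config.n_subjects):
        subject = f"S{s + 1:02d}"
        for r in range(config.n_runs_per_subject):
            latents = band_limited_signals(
                rng, config.k_true, config.n_volumes, config.tr_seconds, config.band
            )
            nuisance = ar1_series(rng, len(NUISANCE_COLUMNS), config.n_volumes)
            voxel_noise = rng.standard_normal((config.n_voxels, config.n_volumes))
            seed_noise = rng.standard_normal((config.n_seeds, config.n_volumes))
            data = amp * latents[labels - 1]
            data = data + config.nuisance_amplitude * (loadings @ nuisance)
            if not noise_free:
                data = data + voxel_noise
            seed_ts = config.seed_mixing.T @ latents
            if not noise_free:
                seed_ts = seed_ts + _SEED_NOISE_SD * seed_noise
            runs.append(
                VoxelTimeSeriesRun(
                    data=data,
                    nuisance=nuisance.T,
                    tr_seconds=config.tr_seconds,
                    subject_id=subject,
                    run_id=f"{subject}_run{r + 1:02d}",
                    fixation_fraction=1.0,
                )
            )
            seeds.append(seed_ts)
    return RestDataset(runs=runs, seeds=seeds, truth=truth)


def generate_null_fingerprint_pair(
    n_seeds: int,
    n_subjects: int,
    noise_sd: float,
    rng_seed: int = 0,
) -> tuple[list[Fingerprint], list[Fingerprint]]:
    """Two per-subject fingerprint sets drawn around one shared mean vector.

    Both clusters' fingerprints are i.i.d. Gaussian perturbations of the
    same population mean, so any rejection of 'same fingerprint' is a type-I
    error; used to calibrate the permutation test.
    """
    if n_subjects < 2:
        raise ValueError("permutation null needs at least 2 subjects")
    rng = np.random.default_rng(rng_seed)
    mean = rng.uniform(0.0, 1.0, size=n_seeds)
    fps_a, fps_b = [], []
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        fps_a.append(
            Fingerprint(subject, 1, mean + noise_sd * rng.standard_normal(n_seeds))
        )
        fps_b.append(
            Fingerprint(subject, 2, mean + noise_sd * rng.standard_normal(n_seeds))
        )
    return fps_a, fps_b


def generate_task_dataset(
    design: BlockDesign,
    truth: GroundTruth,
    hrf_kind: str,
    noise_sd: float,
    rng_seed: int = 0,
    n_runs: int = 1,
    baseline: float = 100.0,
    subject_id: str = "S01",
) -> list[VoxelTimeSeriesRun]:
    """Task runs with planted per-community percent-signal-change effects.

    ``truth.planted_effects`` maps condition name to a length-``k_true``
    array of effect sizes in percent signal change. The voxel signal is
    ``baseline * (1 + sum_cond effect/100 * regressor/peak) + noise`` with
    the same convolved regressors the GLM uses, so noise-free recovery is
    exact. The contrast-agent response is sign-inverted internally.
    """
    x, names = hrf_regressors(design, hrf_kind)  # raises on unknown kind
    rng = np.random.default_rng(rng_seed)
    n_vox = truth.labels.size
    runs = []
    for r in range(n_runs):
        signal = np.ones((n_vox, design.n_volumes))
        for cond, effects in truth.planted_effects.items():
            effects = np.asarray(effects, dtype=float)
            if effects.shape != (truth.k_true,):
                raise ValueError(
                    f"planted effects for {cond!r} must have length {truth.k_true}"
                )
            col = x[:, names.index(cond)]
            peak = regressor_peak(col)
            if peak == 0:
                continue
            per_voxel = effects[truth.labels - 1]
            signal = signal + np.outer(per_voxel / 100.0, col / peak)
        data = baseline * signal
        if noise_sd > 0:
            data = data + noise_sd * rng.standard_normal(data.shape)
        runs.append(
            VoxelTimeSeriesRun(
                data=data,
                nuisance=np.zeros((design.n_volumes, 0)),
                tr_seconds=design.tr_seconds,
                subject_id=subject_id,
                run_id=f"{subject_id}_task{r + 1:02d}",
                fixation_fraction=1.0,
            )
        )
    return runs
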