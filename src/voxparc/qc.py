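"""Run-level quality control and per-run signal conditioning.

Inclusion filters (fixation fraction, mean-correlation outliers) plus the
two conditioning steps applied before any connectivity computation:
zero-phase band-pass filtering and nuisance regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal


@dataclass
class VoxelTimeSeriesRun:
    """One run's mask-voxel-by-time matrix with nuisance series and metadata.

    Parameters
    ----------
    data
        Array of shape ``(n_voxels, n_timepoints)`` in arbitrary signal units.
    nuisance
        Array of shape ``(n_timepoints, q)``: typically white-matter mean,
        ventricle mean and six head-motion parameters.
    tr_seconds
        Sampling interval between volumes.
    subject_id, run_id
        Provenance tokens.
    fixation_fraction
        Fraction of the run spent fixating, in [0, 1]; ``None`` if unknown.
    """

    data: np.ndarray
    nuisance: np.ndarray
    tr_seconds: float
    subject_id: str
    run_id: str
    fixation_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.nuisance = np.asarray(self.nuisance, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2 or self.data.shape[1] < 8:
            raise ValueError(
                f"run {self.run_id!r}: data must be (>=2 voxels, >=8 timepoints), "
                f"got {self.data.shape}"
            )
        if self.nuisance.ndim != 2 or self.nuisance.shape[0] != self.data.shape[1]:
            raise ValueError(
                f"run {self.run_id!r}: nuisance rows ({self.nuisance.shape[0]}) "
                f"must equal data columns ({self.data.shape[1]})"
            )
        if self.tr_seconds <= 0:
            raise ValueError(f"run {self.run_id!r}: tr_seconds must be positive")
        if self.fixation_fraction is not None and not (0.0 <= self.fixation_fraction <= 1.0):
            raise ValueError(
                f"run {self.run_id!r}: fixation_fraction must be in [0, 1]"
            )

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class ExclusionRecord:
    run_id: str
    subject_id: str
    reason: str
    value: Optional[float] = None


@dataclass
class ExclusionLog:
    """Per-run bookkeeping for the inclusion filters."""

    excluded: list[ExclusionRecord] = field(default_factory=list)
    statistics: dict[str, float] = field(default_factory=dict)

    def as_records(self) -> list[dict]:
        return [vars(r) for r in self.excluded]


def filter_by_fixation(
    runs: Sequence[VoxelTimeSeriesRun], threshold: float = 0.85
) -> tuple[list[VoxelTimeSeriesRun], ExclusionLog]:
    """Retain runs whose fixation fraction is at or above ``threshold``.

    A run exactly at the threshold is retained: only runs strictly below are
    excluded.
    """
    log = ExclusionLog()
    retained = []
    for run in runs:
        if run.fixation_fraction is None:
            raise ValueError(f"run {run.run_id!r} has no fixation_fraction set")
        log.statistics[run.run_id] = run.fixation_fraction
        if run.fixation_fraction >= threshold:
            retained.append(run)
        else:
            log.excluded.append(
                ExclusionRecord(
                    run.run_id,
                    run.subject_id,
                    f"fixation_fraction {run.fixation_fraction:.3f} below "
                    f"threshold {threshold:.3f}",
                    run.fixation_fraction,
                )
            )
    return retained, log


def mean_pairwise_correlation(data: np.ndarray) -> float:
    """Mean of all pairwise voxel Pearson correlations (upper triangle)."""
    data = np.asarray(data, dtype=float)
    sd = data.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"voxel {bad} has constant time series; correlation undefined")
    c = np.corrcoef(data)
    iu = np.triu_indices(data.shape[0], k=1)
    return float(c[iu].mean())


def mean_global_signal_correlation(data: np.ndarray) -> float:
    """Mean correlation of each voxel with the global mean time course.

    Alternative reading of the run-level statistic; pairwise is the default.
    """
    data = np.asarray(data, dtype=float)
    sd = data.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"voxel {bad} has constant time series; correlation undefined")
    g = data.mean(axis=0)
    gs = g - g.mean()
    dn = data - data.mean(axis=1, keepdims=True)
    r = dn @ gs / (np.linalg.norm(dn, axis=1) * np.linalg.norm(gs))
    return float(r.mean())


def filter_by_mean_correlation(
    runs: Sequence[VoxelTimeSeriesRun], statistic: str = "pairwise"
) -> tuple[list[VoxelTimeSeriesRun], ExclusionLog]:
    """Exclude runs whose mean-correlation statistic is an outlier.

    The per-run statistic is compared against the median ``m`` across runs;
    runs with values below ``m / 2`` or above ``2 * m`` are excluded
    (symmetric two-times-median rule).
    """
    if len(runs) < 3:
        raise ValueError("filter_by_mean_correlation needs at least 3 runs")
    stat_fn = {
        "pairwise": mean_pairwise_correlation,
        "global": mean_global_signal_correlation,
    }.get(statistic)
    if stat_fn is None:
        raise ValueError(f"unknown statistic {statistic!r}")
    values = np.array([stat_fn(run.data) for run in runs])
    m = float(np.median(values))
    lo, hi = sorted((m / 2.0, 2.0 * m))  # handles negative medians
    log = ExclusionLog()
    retained = []
    for run, v in zip(runs, values):
        log.statistics[run.run_id] = float(v)
        if lo <= v <= hi:
            retained.append(run)
        else:
            log.excluded.append(
                ExclusionRecord(
                    run.run_id,
                    run.subject_id,
                    f"mean correlation {v:.4f} outside [{lo:.4f}, {hi:.4f}] "
                    f"(median {m:.4f})",
                    float(v),
                )
            )
    return retained, log


def design_bandpass_sos(
    low_hz: float, high_hz: float, tr_seconds: float, order: int = 4
) -> np.ndarray:
    """Butterworth band-pass filter in second-order-sections form."""
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz {high_hz} must be below the Nyquist frequency {nyquist}"
        )
    return signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds, output="sos"
    )


def bandpass(
    run: VoxelTimeSeriesRun,
    low_hz: float = 0.0025,
    high_hz: float = 0.05,
    order: int = 4,
) -> VoxelTimeSeriesRun:
    """Zero-phase band-pass of voxel data and nuisance columns.

    Forward-backward Butterworth filtering; the mean (DC component) is
    removed explicitly in addition to the filter's own stop band.
    """
    sos = design_bandpass_sos(low_hz, high_hz, run.tr_seconds, order=order)
    data = run.data - run.data.mean(axis=1, keepdims=True)
    data = signal.sosfiltfilt(sos, data, axis=1)
    data -= data.mean(axis=1, keepdims=True)  # edge effects leave residual DC
    nuis = run.nuisance - run.nuisance.mean(axis=0, keepdims=True)
    if nuis.shape[1] > 0:
        nuis = signal.sosfiltfilt(sos, nuis, axis=0)
        nuis -= nuis.mean(axis=0, keepdims=True)
    return replace(run, data=data, nuisance=nuis)


def _collinear_columns(x: np.ndarray) -> list[int]:
    # columns whose removal restores full rank, via tiny R-diagonal of QR
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    return [int(i) for i in np.flatnonzero(diag <= tol)]


def regress_nuisance(run: VoxelTimeSeriesRun) -> np.ndarray:
    """OLS residual of every voxel against [intercept | nuisance columns].

    Returns the ``(n_voxels, n_timepoints)`` residual matrix; residuals are
    orthogonal to the intercept and to every nuisance column.
    """
    n_t = run.n_timepoints
    x = np.column_stack([np.ones(n_t), run.nuisance])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_columns(x)
        # column 0 is the intercept; report nuisance indices
        bad_nuis = [i - 1 for i in bad if i > 0]
        raise ValueError(
            f"run {run.run_id!r}: nuisance matrix rank-deficient "
            f"(collinear nuisance columns: {bad_nuis})"
        )
    beta, *_ = np.linalg.lstsq(x, run.data.T, rcond=None)
    return run.data - (x @ beta).T
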