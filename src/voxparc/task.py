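"""Block designs, HRF convolution, per-run GLMs and ROI percent signal change.

Supports both contrast-agent (iron-oxide, signal-inverting) and BOLD
hemodynamic responses. ROI statistics follow the beta-ratio percent-signal-
change convention: the condition-minus-control beta difference is scaled by
the peak of the unit-amplitude convolved block regressor and expressed as a
percentage of the intercept (baseline) beta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class BlockDesign:
    """A run's condition timeline on a fixed volume grid."""

    conditions: list[str]
    events: list[tuple[str, float, float]]  # (condition, onset_s, duration_s)
    tr_seconds: float
    n_volumes: int
    start_volumes: int = 0

    def __post_init__(self) -> None:
        total = self.n_volumes * self.tr_seconds
        last_end = 0.0
        for cond, onset, dur in sorted(self.events, key=lambda e: e[1]):
            if onset < last_end - 1e-9:
                raise ValueError(f"event {cond!r} at {onset}s overlaps the previous one")
            last_end = onset + dur
        if last_end > total + 1e-9:
            raise ValueError(
                f"events end at {last_end}s but the run holds only {total}s"
            )

    @property
    def duration_seconds(self) -> float:
        return self.n_volumes * self.tr_seconds


def volumes_for_duration(duration_seconds: float, tr_seconds: float) -> int:
    """Number of volumes in a continuous acquisition of the given duration."""
    n = duration_seconds / tr_seconds
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"duration {duration_seconds}s is not a whole number of TRs ({tr_seconds}s)"
        )
    return int(round(n))


def build_block_design(
    blocks: Sequence[tuple[str, float]],
    tr_seconds: float,
    start_volumes: int = 5,
    repeats: int = 1,
    n_volumes: Optional[int] = None,
) -> BlockDesign:
    """Lay out a repeated block sequence after the start volumes.

    ``blocks`` is the ordered (condition, duration_s) sequence presented
    ``repeats`` times in total. When ``n_volumes`` is omitted it is derived
    as start volumes plus the repeated sequence; when given explicitly the
    events only need to fit within it (the discrepancy is recorded).
    """
    for cond, dur in blocks:
        if abs(dur / tr_seconds - round(dur / tr_seconds)) > 1e-9:
            raise ValueError(
                f"block {cond!r} duration {dur}s is not divisible by TR {tr_seconds}s"
            )
    events = []
    t = start_volumes * tr_seconds
    for _ in range(repeats):
        for cond, dur in blocks:
            events.append((cond, t, float(dur)))
            t += dur
    derived = volumes_for_duration(t, tr_seconds)
    if n_volumes is None:
        n_volumes = derived
    elif n_volumes < derived:
        raise ValueError(
            f"events need {derived} volumes but n_volumes={n_volumes} was given"
        )
    conditions = sorted({c for c, _ in blocks})
    return BlockDesign(
        conditions=conditions,
        events=events,
        tr_seconds=tr_seconds,
        n_volumes=int(n_volumes),
        start_volumes=start_volumes,
    )


# ---------------------------------------------------------------------------
# hemodynamic response functions

#: default gamma-variate parameters (shape, scale_s) for the contrast-agent
#: impulse response; slow dynamics, sign-inverted relative to BOLD
MION_GAMMA = (3.0, 4.0)
MION_DURATION_S = 60.0
BOLD_DURATION_S = 32.0


def hrf_kernel(hrf_kind: str, tr_seconds: float, flip_mion: bool = True) -> np.ndarray:
    """Impulse response sampled at the TR, normalized to unit absolute sum.

    The MION response is negative (contrast agent decreases signal on
    activation); with ``flip_mion`` the sign convention is flipped so that
    condition betas stay positive-for-activation.
    """
    if hrf_kind == "mion":
        t = np.arange(0, MION_DURATION_S + tr_seconds / 2, tr_seconds)
        shape, scale = MION_GAMMA
        h = stats.gamma.pdf(t, a=shape, scale=scale)
        h = -h / h.sum()
        if flip_mion:
            h = -h
        return h
    if hrf_kind == "bold":
        t = np.arange(0, BOLD_DURATION_S + tr_seconds / 2, tr_seconds)
        peak = stats.gamma.pdf(t, a=6, scale=1.0)
        undershoot = stats.gamma.pdf(t, a=16, scale=1.0)
        h = peak - undershoot / 6.0
        return h / h.sum()
    raise ValueError(f"unknown hrf_kind {hrf_kind!r} (expected 'mion' or 'bold')")


def boxcar(design: BlockDesign, condition: str) -> np.ndarray:
    """Unit-amplitude volume-grid indicator of a condition's blocks."""
    x = np.zeros(design.n_volumes)
    tr = design.tr_seconds
    for cond, onset, dur in design.events:
        if cond != condition:
            continue
        i0 = int(round(onset / tr))
        i1 = int(round((onset + dur) / tr))
        x[i0:i1] = 1.0
    return x


def hrf_regressors(
    design: BlockDesign, hrf_kind: str, flip_mion: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Convolved condition regressors, truncated to the run length.

    Returns ``(X, names)`` with ``X`` of shape ``(n_volumes, n_conditions)``.
    A condition with no events yields an all-zero column.
    """
    h = hrf_kernel(hrf_kind, design.tr_seconds, flip_mion=flip_mion)
    cols = []
    for cond in design.conditions:
        x = np.convolve(boxcar(design, cond), h)[: design.n_volumes]
        cols.append(x)
    return np.column_stack(cols), list(design.conditions)


def regressor_peak(x: np.ndarray) -> float:
    """Peak of a unit-amplitude convolved regressor (PSC scaling factor)."""
    return float(np.abs(x).max())


# ---------------------------------------------------------------------------
# GLM


@dataclass
class GLMFit:
    """OLS fit of [condition regressors | nuisance | intercept]."""

    betas: np.ndarray  # (n_targets, n_regressors)
    names: list[str]
    design: np.ndarray  # (n_volumes, n_regressors)
    residual_variance: np.ndarray  # (n_targets,)
    dof: int
    nuisance_count: int

    def __post_init__(self) -> None:
        self.betas = np.atleast_2d(np.asarray(self.betas, dtype=float))
        self.residual_variance = np.atleast_1d(
            np.asarray(self.residual_variance, dtype=float)
        )

    @property
    def intercept_index(self) -> int:
        return self.names.index("intercept")

    def beta(self, name: str) -> np.ndarray:
        return self.betas[:, self.names.index(name)]

    def regressor(self, name: str) -> np.ndarray:
        return self.design[:, self.names.index(name)]


def fit_glm(
    data: np.ndarray,
    regressors: np.ndarray,
    names: Sequence[str],
    nuisance: Optional[np.ndarray] = None,
) -> GLMFit:
    """Per-target OLS against conditions, nuisance columns and an intercept.

    ``data`` is ``(n_targets, n_volumes)`` or a single time course.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    regressors = np.asarray(regressors, dtype=float)
    n_vol = regressors.shape[0]
    if data.shape[1] != n_vol:
        raise ValueError("data length does not match the regressor grid")
    columns = [regressors]
    all_names = list(names)
    q = 0
    if nuisance is not None and np.size(nuisance) > 0:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.shape[0] != n_vol:
            raise ValueError("nuisance rows must match the regressor grid")
        columns.append(nuisance)
        q = nuisance.shape[1]
        all_names += [f"nuisance_{i}" for i in range(q)]
    columns.append(np.ones((n_vol, 1)))
    all_names.append("intercept")
    x = np.column_stack(columns)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = [all_names[i] for i in np.flatnonzero(diag <= tol)]
        raise ValueError(f"design matrix is rank deficient (columns: {bad})")
    beta, *_ = np.linalg.lstsq(x, data.T, rcond=None)
    resid = data - (x @ beta).T
    dof = n_vol - x.shape[1]
    resvar = (resid**2).sum(axis=1) / max(dof, 1)
    return GLMFit(
        betas=beta.T,
        names=all_names,
        design=x,
        residual_variance=resvar,
        dof=dof,
        nuisance_count=q,
    )


def percent_signal_change(fit: GLMFit, condition: str, control: str) -> np.ndarray:
    """Beta-ratio percent signal change of a condition against its control.

    PSC = 100 * (beta_condition - beta_control) * peak(unit regressor)
    / beta_intercept. Returns one value per fitted target.
    """
    b0 = fit.beta("intercept")
    if np.any(b0 <= 0):
        raise ValueError("intercept beta <= 0: nonphysical baseline")
    if condition == control:
        return np.zeros(fit.betas.shape[0])
    peak = regressor_peak(fit.regressor(condition))
    return 100.0 * (fit.beta(condition) - fit.beta(control)) * peak / b0


def contrast_tstats(fit: GLMFit, contrast: Mapping[str, float]) -> np.ndarray:
    """t statistics of a named linear contrast of betas, per target."""
    c = np.zeros(len(fit.names))
    for name, w in contrast.items():
        c[fit.names.index(name)] = w
    xtx_inv = np.linalg.pinv(fit.design.T @ fit.design)
    scale = float(c @ xtx_inv @ c)
    se = np.sqrt(fit.residual_variance * scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(se > 0, fit.betas @ c / se, 0.0)


def select_responsive_voxels(
    fit: GLMFit,
    conditions: Sequence[str],
    p_threshold: float = 0.05,
) -> np.ndarray:
    """Voxels responding to the given conditions versus implicit baseline.

    Keeps voxels whose summed-condition contrast is positive at the
    one-tailed uncorrected threshold; an empty result is flagged with a
    warning and must be skipped downstream.
    """
    t = contrast_tstats(fit, {c: 1.0 for c in conditions})
    p = stats.t.sf(t, df=fit.dof)
    mask = p < p_threshold
    if not mask.any():
        warnings.warn("no responsive voxels at the configured threshold; empty ROI")
    return mask


@dataclass
class PSCStats:
    """Per-ROI percent-signal-change statistics across runs."""

    roi_id: str
    contrast: tuple[str, str]
    per_run_psc: np.ndarray
    mean: float
    sem: float
    t: float
    p_raw: float
    p_fdr: float = np.nan

    @property
    def significant(self) -> bool:
        return self.p_fdr < 0.05

    @property
    def significant_uncorrected(self) -> bool:
        return self.p_raw < 0.05


def psc_ttest_fdr(
    psc_by_roi: Mapping[str, np.ndarray],
    contrast: tuple[str, str] = ("condition", "control"),
    alpha: float = 0.05,
) -> list[PSCStats]:
    """One-tailed one-sample t per ROI with Benjamini-Hochberg adjustment.

    H1: mean PSC > 0. The BH correction runs across the ROIs of one cluster
    solution; both raw and adjusted p-values are reported.
    """
    out = []
    for roi, values in psc_by_roi.items():
        values = np.asarray(values, dtype=float)
        if values.size < 2:
            raise ValueError(f"ROI {roi!r} has fewer than 2 runs")
        res = stats.ttest_1samp(values, 0.0, alternative="greater")
        sem = float(values.std(ddof=1) / np.sqrt(values.size))
        t = float(res.statistic) if np.isfinite(res.statistic) else 0.0
        p = float(res.pvalue) if np.isfinite(res.pvalue) else 0.5
        out.append(
            PSCStats(
                roi_id=str(roi),
                contrast=contrast,
                per_run_psc=values,
                mean=float(values.mean()),
                sem=sem,
                t=t,
                p_raw=p,
            )
        )
    raw = [s.p_raw for s in out]
    _, adjusted, _, _ = multipletests(raw, alpha=alpha, method="fdr_bh")
    for s, p_adj in zip(out, adjusted):
        s.p_fdr = float(p_adj)
    return out
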