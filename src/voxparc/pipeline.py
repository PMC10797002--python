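"""End-to-end wiring: QC -> connectivity -> clustering -> validation."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .clustering import ClusterSolution, LinkageTree, cut_range, linkage_upgma
from .connectivity import (
    DistanceMatrix,
    GroupZMatrix,
    average_group,
    fisher_z,
    profile_distance,
    run_connectivity,
)
from .qc import (
    VoxelTimeSeriesRun,
    bandpass,
    filter_by_fixation,
    filter_by_mean_correlation,
    regress_nuisance,
)
from .validation import ValidationReport, validate_solutions


@dataclass
class ParcellationResult:
    """Everything the validation and reporting stages need."""

    gz: GroupZMatrix
    distance: DistanceMatrix
    tree: LinkageTree
    solutions: dict[int, ClusterSolution]
    conditioned_runs: list[VoxelTimeSeriesRun]
    conditioned_seeds: list[np.ndarray]
    qc_logs: dict


def apply_qc(
    runs: Sequence[VoxelTimeSeriesRun],
    seeds: Optional[Sequence[np.ndarray]] = None,
    fixation_threshold: float = 0.85,
    mean_correlation_statistic: str = "pairwise",
):
    """Both run-inclusion filters, keeping seed arrays aligned with runs."""
    kept, fix_log = filter_by_fixation(runs, threshold=fixation_threshold)
    kept, corr_log = filter_by_mean_correlation(
        kept, statistic=mean_correlation_statistic
    )
    logs = {"fixation": fix_log, "mean_correlation": corr_log}
    if seeds is None:
        return kept, None, logs
    by_id = {run.run_id: ts for run, ts in zip(runs, seeds)}
    return kept, [by_id[r.run_id] for r in kept], logs


def condition_run(
    run: VoxelTimeSeriesRun,
    seed_ts: Optional[np.ndarray] = None,
    low_hz: float = 0.0025,
    high_hz: float = 0.05,
    order: int = 4,
):
    """Band-pass then nuisance-regress one run (and its seed series)."""
    bp = bandpass(run, low_hz=low_hz, high_hz=high_hz, order=order)
    conditioned = replace(bp, data=regress_nuisance(bp))
    if seed_ts is None:
        return conditioned, None
    seed_run = replace(
        bp, data=np.asarray(seed_ts, dtype=float), run_id=run.run_id + "_seeds"
    )
    bp_seed = bandpass(seed_run, low_hz=low_hz, high_hz=high_hz, order=order)
    return conditioned, regress_nuisance(bp_seed)


def parcellate(
    runs: Sequence[VoxelTimeSeriesRun],
    seeds: Optional[Sequence[np.ndarray]] = None,
    k_range: Sequence[int] = range(2, 11),
    low_hz: float = 0.0025,
    high_hz: float = 0.05,
    filter_order: int = 4,
    fixation_threshold: float = 0.85,
    apply_filters: bool = True,
) -> ParcellationResult:
    """Full resting-state parcellation up to the nested cluster solutions."""
    logs: dict = {}
    if apply_filters:
        runs, seeds, logs = apply_qc(runs, seeds, fixation_threshold=fixation_threshold)
    conditioned_runs: list[VoxelTimeSeriesRun] = []
    conditioned_seeds: list[np.ndarray] = []
    per_subject_z: dict[str, list[np.ndarray]] = {}
    for i, run in enumerate(runs):
        seed_ts = None if seeds is None else seeds[i]
        cond, cond_seed = condition_run(
            run, seed_ts, low_hz=low_hz, high_hz=high_hz, order=filter_order
        )
        conditioned_runs.append(cond)
        if cond_seed is not None:
            conditioned_seeds.append(cond_seed)
        bp = bandpass(run, low_hz=low_hz, high_hz=high_hz, order=filter_order)
        z = fisher_z(run_connectivity(bp))
        np.fill_diagonal(z, 0.0)
        per_subject_z.setdefault(run.subject_id, []).append(z)
    gz = average_group(per_subject_z)
    d = profile_distance(gz)
    tree = linkage_upgma(d)
    k_range = [k for k in k_range if k <= gz.n_voxels]
    solutions = cut_range(tree, k_range)
    return ParcellationResult(
        gz=gz,
        distance=d,
        tree=tree,
        solutions=solutions,
        conditioned_runs=conditioned_runs,
        conditioned_seeds=conditioned_seeds,
        qc_logs=logs,
    )


def validate_parcellation(
    result: ParcellationResult,
    alpha: float = 0.05,
    n_perm: int = 100_000,
    rng_seed: int = 0,
) -> ValidationReport:
    """All three cluster-validation criteria on a parcellation result."""
    if not result.conditioned_seeds:
        raise ValueError("validation needs seed time series")
    return validate_solutions(
        result.tree,
        result.gz,
        result.distance,
        result.conditioned_runs,
        result.conditioned_seeds,
        k_range=sorted(result.solutions),
        alpha=alpha,
        n_perm=n_perm,
        rng_seed=rng_seed,
    )
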