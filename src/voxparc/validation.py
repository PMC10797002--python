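"""Cluster-count selection via fingerprints, silhouette and the elbow rule.

A cluster's fingerprint is its vector of Fisher-z correlations with a fixed
set of external seed time series, computed per subject by averaging over
runs. Fingerprints of two clusters are compared by cosine similarity of the
min-max normalized group means; significance comes from a subject-level
label-swap permutation test (exact enumeration when feasible). Silhouette
and the within-cluster sum-of-squares elbow provide the two remaining
votes, combined by ``consensus_k``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import silhouette_score

from .clustering import ClusterSolution, LinkageTree, cut_tree
from .connectivity import DistanceMatrix, GroupZMatrix, fisher_z
from .qc import VoxelTimeSeriesRun


@dataclass
class Fingerprint:
    """Per-subject, per-cluster vector of run-averaged z-correlations to seeds."""

    subject_id: str
    cluster_id: int
    z_to_seeds: np.ndarray
    normalized: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.z_to_seeds = np.asarray(self.z_to_seeds, dtype=float).ravel()


@dataclass
class PairwiseSimilarityResult:
    cluster_a: int
    cluster_b: int
    cosine: float
    p_value: float
    n_permutations: int
    exact: bool


@dataclass
class ValidationReport:
    """All three criteria over the K range plus the consensus choice."""

    k_range: list[int]
    pairwise: dict[int, list[PairwiseSimilarityResult]]
    silhouette: dict[int, float]
    wss: dict[int, float]
    fingerprint_k: int = 0
    elbow_k: int = 0
    silhouette_k: int = 0
    chosen_k: int = 0
    rationale: str = ""
    alpha: float = 0.05
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "k_range": self.k_range,
            "alpha": self.alpha,
            "pairwise": {
                str(k): [
                    {
                        "cluster_a": r.cluster_a,
                        "cluster_b": r.cluster_b,
                        "cosine": r.cosine,
                        "p_value": r.p_value,
                        "n_permutations": r.n_permutations,
                        "exact": r.exact,
                        "significant": r.p_value < self.alpha,
                    }
                    for r in results
                ]
                for k, results in self.pairwise.items()
            },
            "silhouette": {str(k): v for k, v in self.silhouette.items()},
            "wss": {str(k): v for k, v in self.wss.items()},
            "votes": {
                "fingerprint": self.fingerprint_k,
                "elbow": self.elbow_k,
                "silhouette": self.silhouette_k,
            },
            "chosen_k": self.chosen_k,
            "rationale": self.rationale,
            "warnings": self.warnings,
        }


# ---------------------------------------------------------------------------
# fingerprints


def compute_fingerprints(
    sol: ClusterSolution,
    runs: Sequence[VoxelTimeSeriesRun],
    seeds: Sequence[np.ndarray],
) -> list[Fingerprint]:
    """Fingerprint of every cluster for every subject.

    ``runs`` must already be band-passed and nuisance-regressed; ``seeds``
    holds, aligned with ``runs``, the ``(n_seeds, n_timepoints)`` seed mean
    time courses of each run. Per run the cluster-mean time course is
    correlated with every seed, Fisher z-transformed, then averaged across
    the subject's runs.
    """
    if len(runs) != len(seeds):
        raise ValueError(f"{len(runs)} runs but {len(seeds)} seed arrays")
    for c in range(1, sol.k + 1):
        if sol.members(c).size == 0:
            raise ValueError(f"cluster {c} is empty")
    per_subject: dict[str, list[np.ndarray]] = {}
    for run, seed_ts in zip(runs, seeds):
        seed_ts = np.asarray(seed_ts, dtype=float)
        if seed_ts.shape[1] != run.n_timepoints:
            raise ValueError(
                f"run {run.run_id!r}: seed series length {seed_ts.shape[1]} "
                f"!= run length {run.n_timepoints}"
            )
        cluster_means = np.stack(
            [run.data[sol.members(c)].mean(axis=0) for c in range(1, sol.k + 1)]
        )
        stacked = np.vstack([cluster_means, seed_ts])
        r = np.corrcoef(stacked)[: sol.k, sol.k:]
        per_subject.setdefault(run.subject_id, []).append(fisher_z(r))
    fingerprints = []
    for subject in sorted(per_subject):
        mean_z = np.mean(per_subject[subject], axis=0)
        for c in range(1, sol.k + 1):
            fingerprints.append(Fingerprint(subject, c, mean_z[c - 1]))
    return fingerprints


def minmax_normalize(v: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1]; a constant vector maps to all-0.5 (see decisions)."""
    v = np.asarray(v, dtype=float)
    lo, hi = v.min(axis=-1, keepdims=True), v.max(axis=-1, keepdims=True)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    return np.where(span > 0, (v - lo) / safe, 0.5)


def _cosine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    num = (a * b).sum(axis=-1)
    den = np.linalg.norm(a, axis=-1) * np.linalg.norm(b, axis=-1)
    return num / den


def _stack_pair(
    fps_a: Sequence[Fingerprint], fps_b: Sequence[Fingerprint]
) -> tuple[np.ndarray, np.ndarray]:
    """Align the two fingerprint sets on their common subjects."""
    a_by = {f.subject_id: f.z_to_seeds for f in fps_a}
    b_by = {f.subject_id: f.z_to_seeds for f in fps_b}
    common = sorted(set(a_by) & set(b_by))
    if not common:
        raise ValueError("no subject has both fingerprints")
    return (
        np.stack([a_by[s] for s in common]),
        np.stack([b_by[s] for s in common]),
    )


def normalize_and_compare(
    fps_a: Sequence[Fingerprint], fps_b: Sequence[Fingerprint]
) -> float:
    """Observed cosine similarity between two clusters' group fingerprints.

    Subject fingerprints are averaged per cluster, each group mean is
    min-max normalized to [0, 1], and the cosine of the two normalized
    vectors is returned.
    """
    a, b = _stack_pair(fps_a, fps_b)
    return float(_cosine(minmax_normalize(a.mean(0)), minmax_normalize(b.mean(0))))


def _assignment_cosines(a: np.ndarray, b: np.ndarray, swaps: np.ndarray) -> np.ndarray:
    """Cosines for label-swap assignments.

    ``swaps`` is (n_assignments, n_subjects) in {0, 1}; 1 swaps that
    subject's a/b fingerprints before group averaging.
    """
    n = a.shape[0]
    s = swaps.astype(float)
    mean_a = ((1.0 - s) @ a + s @ b) / n
    mean_b = (s @ a + (1.0 - s) @ b) / n
    return _cosine(minmax_normalize(mean_a), minmax_normalize(mean_b))


def permutation_test_pair(
    fps_a: Sequence[Fingerprint],
    fps_b: Sequence[Fingerprint],
    n_perm: int = 100_000,
    rng_seed: int = 0,
    cluster_a: int = 0,
    cluster_b: int = 0,
) -> PairwiseSimilarityResult:
    """Subject-level label-swap permutation test on the pair's cosine.

    Each iteration independently swaps (with probability 1/2) the two
    cluster labels within every subject, recomputes the group means,
    normalization and cosine. Low observed similarity yields a small
    p-value. When ``2 ** n_subjects <= n_perm`` the full swap group is
    enumerated instead of sampled; otherwise the Monte-Carlo p uses the
    add-one correction so p > 0 always.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a, b = _stack_pair(fps_a, fps_b)
    n_sub = a.shape[0]
    if n_sub < 2:
        raise ValueError("permutation test needs >= 2 subjects")
    observed = float(_cosine(minmax_normalize(a.mean(0)), minmax_normalize(b.mean(0))))
    tol = 1e-12
    if 2**n_sub <= n_perm:
        codes = np.arange(2**n_sub)
        swaps = (codes[:, None] >> np.arange(n_sub)) & 1
        cosines = _assignment_cosines(a, b, swaps)
        # identity assignment is part of the group, so p >= 1 / 2**n_sub
        p = float((cosines <= observed + tol).sum() / cosines.size)
        return PairwiseSimilarityResult(
            cluster_a, cluster_b, observed, p, int(cosines.size), exact=True
        )
    rng = np.random.default_rng(rng_seed)
    swaps = rng.integers(0, 2, size=(n_perm, n_sub))
    cosines = _assignment_cosines(a, b, swaps)
    p = float((1 + (cosines <= observed + tol).sum()) / (1 + n_perm))
    return PairwiseSimilarityResult(
        cluster_a, cluster_b, observed, p, n_perm, exact=False
    )


def pairwise_fingerprint_tests(
    fingerprints: Sequence[Fingerprint],
    k: int,
    n_perm: int = 100_000,
    rng_seed: int = 0,
) -> list[PairwiseSimilarityResult]:
    """All K(K-1)/2 pairwise permutation tests for one cluster solution."""
    by_cluster: dict[int, list[Fingerprint]] = {}
    for f in fingerprints:
        by_cluster.setdefault(f.cluster_id, []).append(f)
    results = []
    for i, ca in enumerate(sorted(by_cluster)):
        for cb in sorted(by_cluster)[i + 1:]:
            results.append(
                permutation_test_pair(
                    by_cluster[ca],
                    by_cluster[cb],
                    n_perm=n_perm,
                    rng_seed=rng_seed + 1000 * ca + cb,
                    cluster_a=ca,
                    cluster_b=cb,
                )
            )
    return results


def fingerprint_criterion(
    tree: LinkageTree,
    runs: Sequence[VoxelTimeSeriesRun],
    seeds: Sequence[np.ndarray],
    k_range: Sequence[int] = range(2, 11),
    alpha: float = 0.05,
    n_perm: int = 100_000,
    rng_seed: int = 0,
) -> tuple[int, dict[int, list[PairwiseSimilarityResult]]]:
    """Largest K whose clusters are all pairwise significantly different.

    Returns 1 (and the full p table) when no K in the range qualifies.
    """
    tables: dict[int, list[PairwiseSimilarityResult]] = {}
    best = 1
    for k in k_range:
        sol = cut_tree(tree, k)
        fps = compute_fingerprints(sol, runs, seeds)
        results = pairwise_fingerprint_tests(fps, k, n_perm=n_perm, rng_seed=rng_seed)
        tables[k] = results
        if all(r.p_value < alpha for r in results):
            best = max(best, k)
    return best, tables


# ---------------------------------------------------------------------------
# silhouette and elbow


def silhouette_mean(d: DistanceMatrix, sol: ClusterSolution) -> float:
    """Mean silhouette over voxels from the precomputed distance matrix."""
    if sol.k < 2:
        raise ValueError("silhouette requires K >= 2")
    if sol.n_voxels != d.n_voxels:
        raise ValueError("solution and distance matrix sizes differ")
    return float(silhouette_score(d.d, sol.labels, metric="precomputed"))


def wss_curve(
    gz: GroupZMatrix, sols: Mapping[int, ClusterSolution]
) -> dict[int, float]:
    """Total within-cluster sum of squares per K, in z-profile space."""
    out = {}
    for k, sol in sols.items():
        if sol.n_voxels != gz.n_voxels:
            raise ValueError(f"solution at K={k} does not match the z matrix")
        total = 0.0
        for c in range(1, sol.k + 1):
            rows = gz.z[sol.members(c)]
            total += float(((rows - rows.mean(axis=0)) ** 2).sum())
        out[k] = total
    return out


def elbow_point(wss: Mapping[int, float]) -> tuple[int, dict]:
    """K maximizing the discrete second difference of the WSS curve.

    Ties pick the smallest K and emit a no-elbow warning; the curve and all
    second differences are returned for reporting.
    """
    ks = sorted(wss)
    if len(ks) < 4:
        raise ValueError("elbow detection needs a curve over >= 4 values of K")
    w = np.array([wss[k] for k in ks])
    second = w[:-2] - 2 * w[1:-1] + w[2:]
    interior = ks[1:-1]
    best_idx = int(np.argmax(second))
    info = {"k": ks, "wss": w.tolist(), "second_difference": second.tolist()}
    near_ties = np.isclose(second, second[best_idx], rtol=1e-9, atol=1e-12)
    if near_ties.sum() > 1:
        best_idx = int(np.flatnonzero(near_ties)[0])
        info["no_elbow"] = True
        warnings.warn("WSS curve has no unique elbow; returning smallest tied K")
    return interior[best_idx], info


def silhouette_vote(silhouette: Mapping[int, float], min_k: int = 3) -> int:
    """Silhouette's vote for consensus: the best local peak at K >= min_k.

    A K is a peak when its mean silhouette exceeds both neighbors; with no
    peak, the global argmax is used.
    """
    ks = sorted(silhouette)
    vals = np.array([silhouette[k] for k in ks])
    peaks = [
        ks[i]
        for i in range(1, len(ks) - 1)
        if vals[i] > vals[i - 1] and vals[i] > vals[i + 1] and ks[i] >= min_k
    ]
    if peaks:
        return max(peaks, key=lambda k: silhouette[k])
    return ks[int(np.argmax(vals))]


def consensus_k(report: ValidationReport) -> ValidationReport:
    """Majority vote among the three criteria; fingerprint wins deadlocks.

    The fingerprint criterion is the only inferential one, so when all
    three votes differ it takes precedence. The rationale records every
    vote.
    """
    votes = [report.fingerprint_k, report.elbow_k, report.silhouette_k]
    counts = {v: votes.count(v) for v in set(votes)}
    majority = [v for v, c in counts.items() if c >= 2]
    if majority:
        chosen = majority[0]
        why = "majority vote"
    else:
        chosen = report.fingerprint_k
        why = "no majority; fingerprint criterion takes precedence"
    report.chosen_k = chosen
    report.rationale = (
        f"fingerprint={report.fingerprint_k}, elbow={report.elbow_k}, "
        f"silhouette={report.silhouette_k} -> K={chosen} ({why})"
    )
    return report


def validate_solutions(
    tree: LinkageTree,
    gz: GroupZMatrix,
    d: DistanceMatrix,
    runs: Sequence[VoxelTimeSeriesRun],
    seeds: Sequence[np.ndarray],
    k_range: Sequence[int] = range(2, 11),
    alpha: float = 0.05,
    n_perm: int = 100_000,
    rng_seed: int = 0,
) -> ValidationReport:
    """Run all three validation criteria and pick the consensus K."""
    k_range = list(k_range)
    sols = {k: cut_tree(tree, k) for k in k_range}
    fp_k, tables = fingerprint_criterion(
        tree, runs, seeds, k_range=k_range, alpha=alpha, n_perm=n_perm, rng_seed=rng_seed
    )
    sil = {k: silhouette_mean(d, sols[k]) for k in k_range}
    wss = wss_curve(gz, sols)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        elbow_k, _ = elbow_point(wss)
    report = ValidationReport(
        k_range=k_range,
        pairwise=tables,
        silhouette=sil,
        wss=wss,
        fingerprint_k=fp_k,
        elbow_k=elbow_k,
        silhouette_k=silhouette_vote(sil),
        alpha=alpha,
        warnings=[str(w.message) for w in caught],
    )
    return consensus_k(report)
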