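from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxparc import (
    ClusterSolution,
    DistanceMatrix,
    Fingerprint,
    GroupZMatrix,
    ValidationReport,
    compute_fingerprints,
    consensus_k,
    elbow_point,
    fisher_z,
    generate_null_fingerprint_pair,
    normalize_and_compare,
    permutation_test_pair,
    silhouette_mean,
    wss_curve,
)
from voxparc.validation import minmax_normalize, silhouette_vote

from conftest import make_run


def fps(values, cluster_id=1):
    return [
        Fingerprint(f"S{i:02d}", cluster_id, np.asarray(v, dtype=float))
        for i, v in enumerate(values)
    ]


def brute_force_pair_p(fps_a, fps_b):
    """Exhaustive enumeration of all per-subject label swaps (oracle)."""
    a = np.stack([f.z_to_seeds for f in fps_a])
    b = np.stack([f.z_to_seeds for f in fps_b])
    n = a.shape[0]

    def cosine(u, v):
        return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))

    def norm01(v):
        span = v.max() - v.min()
        return (v - v.min()) / span if span > 0 else np.full_like(v, 0.5)

    observed = cosine(norm01(a.mean(0)), norm01(b.mean(0)))
    count = total = 0
    for swap in itertools.product([0, 1], repeat=n):
        swap = np.array(swap, dtype=bool)
        ga = np.where(swap[:, None], b, a).mean(0)
        gb = np.where(swap[:, None], a, b).mean(0)
        c = cosine(norm01(ga), norm01(gb))
        count += c <= observed + 1e-12
        total += 1
    return count / total, observed


class TestComputeFingerprints:
    def test_seed_equal_to_cluster_mean_gives_capped_z(self, rng):
        data = rng.standard_normal((4, 60))
        run = make_run(data)
        sol = ClusterSolution(k=2, labels=np.array([1, 1, 2, 2]))
        seed_ts = data[:2].mean(axis=0, keepdims=True)
        out = compute_fingerprints(sol, [run], [seed_ts])
        z_c1 = next(f for f in out if f.cluster_id == 1).z_to_seeds[0]
        assert z_c1 == pytest.approx(fisher_z(1.0))

    def test_independent_seed_near_zero(self, rng):
        data = rng.standard_normal((4, 5000))
        run = make_run(data)
        sol = ClusterSolution(k=2, labels=np.array([1, 1, 2, 2]))
        seed_ts = rng.standard_normal((1, 5000))
        out = compute_fingerprints(sol, [run], [seed_ts])
        assert abs(out[0].z_to_seeds[0]) < 0.1

    def test_run_averaging_within_subject(self, rng):
        sol = ClusterSolution(k=1, labels=np.array([1, 1]))
        runs = [make_run(rng.standard_normal((2, 50)), run_id=f"r{i}") for i in range(2)]
        seeds = [rng.standard_normal((1, 50)) for _ in range(2)]
        out = compute_fingerprints(sol, runs, seeds)
        assert len(out) == 1  # one subject, one cluster
        zs = []
        for run, seed_ts in zip(runs, seeds):
            zs.append(
                compute_fingerprints(sol, [run], [seed_ts])[0].z_to_seeds
            )
        assert np.allclose(out[0].z_to_seeds, np.mean(zs, axis=0))

    def test_planted_mixing_gives_largest_z_for_own_seed(self, small_rest_dataset):
        from voxparc.pipeline import parcellate

        ds = small_rest_dataset
        res = parcellate(ds.runs, ds.seeds, k_range=[4])
        sol = res.solutions[4]
        out = compute_fingerprints(sol, res.conditioned_runs, res.conditioned_seeds)
        # seed 0 couples to community 1 (default mixing): the cluster
        # containing community-1 voxels must carry the largest z to seed 0
        target = sol.labels[np.flatnonzero(ds.truth.labels == 1)[0]]
        by_cluster = {}
        for f in out:
            by_cluster.setdefault(f.cluster_id, []).append(f.z_to_seeds)
        means = {c: np.mean(v, axis=0) for c, v in by_cluster.items()}
        assert max(means, key=lambda c: means[c][0]) == target

    def test_empty_cluster_errors(self, rng):
        run = make_run(rng.standard_normal((3, 50)))
        sol = ClusterSolution(k=3, labels=np.array([1, 2, 3]))
        bad = ClusterSolution(k=3, labels=np.array([1, 2, 3]))
        bad.labels = np.array([1, 1, 2])  # cluster 3 now empty
        with pytest.raises(ValueError, match="empty"):
            compute_fingerprints(bad, [run], [rng.standard_normal((1, 50))])

    def test_seed_run_mismatch_errors(self, rng):
        run = make_run(rng.standard_normal((2, 50)))
        sol = ClusterSolution(k=1, labels=np.array([1, 1]))
        with pytest.raises(ValueError, match="length"):
            compute_fingerprints(sol, [run], [rng.standard_normal((1, 40))])


class TestNormalizeAndCompare:
    def test_identical_fingerprints_cosine_one(self):
        a = fps([[0.1, 0.5, 0.9], [0.2, 0.6, 1.0]], 1)
        b = fps([[0.1, 0.5, 0.9], [0.2, 0.6, 1.0]], 2)
        assert normalize_and_compare(a, b) == pytest.approx(1.0)

    def test_disjoint_support_cosine_zero(self):
        a = fps([[1.0, 0.0, 0.0, 0.0]], 1)
        b = fps([[0.0, 1.0, 0.0, 0.0]], 2)
        assert normalize_and_compare(a, b) == pytest.approx(0.0)

    def test_hand_arithmetic_example(self):
        # group means (0.2, 0.4, 0.6) and (0.6, 0.4, 0.2) normalize to
        # (0, 0.5, 1) and (1, 0.5, 0); cosine = 0.25 / 1.25 = 0.2
        a = fps([[0.2, 0.4, 0.6]], 1)
        b = fps([[0.6, 0.4, 0.2]], 2)
        assert normalize_and_compare(a, b) == pytest.approx(0.2, abs=1e-12)

    def test_constant_fingerprint_fallback(self):
        a = fps([[0.5, 0.5, 0.5]], 1)
        b = fps([[0.0, 0.5, 1.0]], 2)
        # constant maps to all-0.5 instead of erroring
        value = normalize_and_compare(a, b)
        assert np.isfinite(value)

    @given(st.lists(st.floats(min_value=-5, max_value=5), min_size=2, max_size=12))
    def test_minmax_bounds_property(self, values):
        v = minmax_normalize(np.array(values))
        assert np.all(v >= 0.0) and np.all(v <= 1.0)
        if max(values) > min(values):
            assert v.min() == 0.0 and v.max() == pytest.approx(1.0)


class TestPermutationTest:
    def test_identical_sets_p_one(self, rng):
        vals = rng.uniform(0, 1, (4, 6))
        a = fps(vals, 1)
        b = fps(vals, 2)
        res = permutation_test_pair(a, b, n_perm=1000, rng_seed=0)
        assert res.cosine == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_exact_enumeration_two_subjects(self, rng):
        a = fps(rng.uniform(0, 1, (2, 5)), 1)
        b = fps(rng.uniform(0, 1, (2, 5)), 2)
        res = permutation_test_pair(a, b, n_perm=1000, rng_seed=0)
        assert res.exact and res.n_permutations == 4
        expected_p, expected_obs = brute_force_pair_p(a, b)
        assert res.p_value == pytest.approx(expected_p)
        assert res.cosine == pytest.approx(expected_obs)

    @pytest.mark.parametrize("n_sub", [3, 5, 8])
    def test_exact_matches_brute_force(self, n_sub, rng):
        a = fps(rng.uniform(0, 1, (n_sub, 7)), 1)
        b = fps(rng.uniform(0, 1, (n_sub, 7)) + 0.3, 2)
        res = permutation_test_pair(a, b, n_perm=100_000, rng_seed=0)
        expected_p, _ = brute_force_pair_p(a, b)
        assert res.exact
        assert res.p_value == pytest.approx(expected_p)

    def test_monte_carlo_close_to_exact(self, rng):
        # 10 subjects, n_perm below 2^10 forces the sampled path
        a = fps(rng.uniform(0, 1, (10, 6)), 1)
        b = fps(rng.uniform(0, 1, (10, 6)) + 0.15, 2)
        exact = permutation_test_pair(a, b, n_perm=100_000, rng_seed=0)
        assert exact.exact
        mc = permutation_test_pair(a, b, n_perm=500, rng_seed=3)
        assert not mc.exact
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 500)
        assert abs(mc.p_value - exact.p_value) <= 3 * se + 2 / 500

    def test_deterministic_given_seed(self, rng):
        a = fps(rng.uniform(0, 1, (12, 6)), 1)
        b = fps(rng.uniform(0, 1, (12, 6)), 2)
        r1 = permutation_test_pair(a, b, n_perm=300, rng_seed=9)
        r2 = permutation_test_pair(a, b, n_perm=300, rng_seed=9)
        assert r1.p_value == r2.p_value

    def test_requires_two_subjects(self):
        a = fps([[0.1, 0.2]], 1)
        b = fps([[0.3, 0.4]], 2)
        with pytest.raises(ValueError, match="2 subjects"):
            permutation_test_pair(a, b)

    def test_n_perm_validation(self, rng):
        a = fps(rng.uniform(0, 1, (3, 4)), 1)
        b = fps(rng.uniform(0, 1, (3, 4)), 2)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test_pair(a, b, n_perm=0)


class TestNullGenerator:
    def test_noise_free_pair_identical(self):
        a, b = generate_null_fingerprint_pair(6, 4, noise_sd=0.0, rng_seed=0)
        assert np.allclose(
            np.stack([f.z_to_seeds for f in a]), np.stack([f.z_to_seeds for f in b])
        )
        assert normalize_and_compare(a, b) == pytest.approx(1.0)

    def test_two_subjects_enumeration_size(self):
        a, b = generate_null_fingerprint_pair(5, 2, noise_sd=0.1, rng_seed=1)
        res = permutation_test_pair(a, b, n_perm=1000, rng_seed=0)
        assert res.exact and res.n_permutations == 4  # 2^2 assignments

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError):
            generate_null_fingerprint_pair(5, 1, noise_sd=0.1)

    def test_type_one_error_calibrated(self):
        # 2000 null datasets at alpha = 0.05: empirical rejection rate must
        # sit inside the binomial 95% CI around 0.05
        n_datasets, alpha = 2000, 0.05
        rejections = 0
        for i in range(n_datasets):
            a, b = generate_null_fingerprint_pair(23, 8, noise_sd=0.2, rng_seed=i)
            res = permutation_test_pair(a, b, n_perm=2000, rng_seed=i)
            rejections += res.p_value < alpha
        from scipy.stats import binom

        lo, hi = binom.interval(0.95, n_datasets, alpha)
        assert lo <= rejections <= hi


def two_pairs_distance():
    d = np.full((4, 4), 10.0)
    d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 1.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d=d)


class TestSilhouette:
    def test_two_pairs_toy_hand_value(self):
        # a = 1, b = 10 for every point: s = 1 - 1/10 = 0.9
        sol = ClusterSolution(k=2, labels=np.array([1, 1, 2, 2]))
        assert silhouette_mean(two_pairs_distance(), sol) == pytest.approx(0.9)

    def test_separated_blobs_near_one(self):
        d = np.full((6, 6), 1e6)
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
            d[i, j] = d[j, i] = 1.0
        np.fill_diagonal(d, 0.0)
        sol = ClusterSolution(k=2, labels=np.array([1, 1, 1, 2, 2, 2]))
        assert silhouette_mean(DistanceMatrix(d=d), sol) > 0.99

    def test_random_labels_structureless_near_zero(self, rng):
        pts = rng.standard_normal((60, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        sol = ClusterSolution(
            k=2, labels=rng.permutation(np.repeat([1, 2], 30))
        )
        assert abs(silhouette_mean(DistanceMatrix(d=d), sol)) < 0.1

    def test_k_one_errors(self):
        sol = ClusterSolution(k=1, labels=np.ones(4, dtype=int))
        with pytest.raises(ValueError):
            silhouette_mean(two_pairs_distance(), sol)

    def test_consistent_permutation_invariance(self, rng):
        pts = rng.standard_normal((12, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = rng.integers(1, 4, 12)
        labels[:3] = [1, 2, 3]  # ensure all ids present
        sol = ClusterSolution(k=3, labels=labels)
        s1 = silhouette_mean(DistanceMatrix(d=d), sol)
        perm = rng.permutation(12)
        sol_p = ClusterSolution(k=3, labels=labels[perm])
        s2 = silhouette_mean(DistanceMatrix(d=d[np.ix_(perm, perm)]), sol_p)
        assert s1 == pytest.approx(s2, abs=1e-12)


def make_gz(z):
    z = np.asarray(z, dtype=float)
    z = (z + z.T) / 2
    np.fill_diagonal(z, 0.0)
    return GroupZMatrix(z=z, n_subjects=1, n_runs_per_subject={"A": 1})


class TestWss:
    def test_k_equals_n_voxels_zero(self, rng):
        gz = make_gz(rng.standard_normal((5, 5)))
        sol = ClusterSolution(k=5, labels=np.arange(1, 6))
        assert wss_curve(gz, {5: sol})[5] == pytest.approx(0.0)

    def test_k_one_total_sum_of_squares(self, rng):
        gz = make_gz(rng.standard_normal((6, 6)))
        sol = ClusterSolution(k=1, labels=np.ones(6, dtype=int))
        expected = ((gz.z - gz.z.mean(axis=0)) ** 2).sum()
        assert wss_curve(gz, {1: sol})[1] == pytest.approx(expected)

    def test_two_pairs_toy_matches_brute_force(self, rng):
        gz = make_gz(rng.standard_normal((4, 4)))
        sol = ClusterSolution(k=2, labels=np.array([1, 1, 2, 2]))
        expected = 0.0
        for members in ([0, 1], [2, 3]):
            rows = gz.z[members]
            centroid = rows.mean(axis=0)
            for row in rows:
                expected += ((row - centroid) ** 2).sum()
        assert wss_curve(gz, {2: sol})[2] == pytest.approx(expected)

    def test_label_matrix_mismatch_errors(self, rng):
        gz = make_gz(rng.standard_normal((4, 4)))
        sol = ClusterSolution(k=2, labels=np.array([1, 1, 2, 2, 2]))
        with pytest.raises(ValueError):
            wss_curve(gz, {2: sol})

    def test_nonincreasing_along_nested_solutions(self, rng):
        from voxparc import cut_range, linkage_upgma, profile_distance

        gz = make_gz(rng.standard_normal((12, 12)))
        tree = linkage_upgma(profile_distance(gz))
        sols = cut_range(tree, range(1, 13))
        wss = wss_curve(gz, sols)
        values = [wss[k] for k in sorted(wss)]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))
        assert wss[12] == pytest.approx(0.0)


class TestElbow:
    def test_constructed_kink_at_four(self):
        # piecewise linear: steep slope until K=4, shallow after
        wss = {2: 100.0, 3: 60.0, 4: 20.0, 5: 18.0, 6: 16.0, 7: 14.0}
        k, info = elbow_point(wss)
        assert k == 4
        assert "second_difference" in info

    def test_strictly_linear_flags_no_elbow(self):
        wss = {k: 100.0 - 10.0 * k for k in range(2, 8)}
        with pytest.warns(UserWarning, match="no unique elbow"):
            k, info = elbow_point(wss)
        assert k == 3  # smallest interior K on ties
        assert info.get("no_elbow")

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            elbow_point({2: 3.0, 3: 2.0, 4: 1.0})

    def test_planted_k3_recovered(self):
        from voxparc import SyntheticConfig, cut_range, generate_rest_dataset
        from voxparc.pipeline import parcellate

        cfg = SyntheticConfig(
            n_voxels=36, k_true=3, n_seeds=9, n_subjects=2, n_runs_per_subject=2,
            n_volumes=150, rng_seed=11,
        )
        ds = generate_rest_dataset(cfg)
        res = parcellate(ds.runs, ds.seeds, k_range=range(2, 9))
        wss = wss_curve(res.gz, res.solutions)
        k, _ = elbow_point(wss)
        assert k == 3


class TestConsensus:
    def _report(self, fp, elbow, sil):
        return ValidationReport(
            k_range=[2, 3, 4, 5],
            pairwise={},
            silhouette={},
            wss={},
            fingerprint_k=fp,
            elbow_k=elbow,
            silhouette_k=sil,
        )

    def test_majority_vote(self):
        report = consensus_k(self._report(4, 4, 2))
        assert report.chosen_k == 4
        assert "majority" in report.rationale

    def test_no_majority_fingerprint_precedence(self):
        report = consensus_k(self._report(4, 5, 2))
        assert report.chosen_k == 4
        assert "precedence" in report.rationale

    def test_rationale_records_votes(self):
        report = consensus_k(self._report(3, 5, 5))
        assert report.chosen_k == 5
        for fragment in ("fingerprint=3", "elbow=5", "silhouette=5"):
            assert fragment in report.rationale

    def test_silhouette_vote_prefers_local_peak(self):
        sil = {2: 0.8, 3: 0.5, 4: 0.6, 5: 0.55, 6: 0.4}
        assert silhouette_vote(sil) == 4

    def test_silhouette_vote_falls_back_to_argmax(self):
        sil = {2: 0.8, 3: 0.7, 4: 0.6, 5: 0.5}
        assert silhouette_vote(sil) == 2
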