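import numpy as np
import pytest

from conftest import make_space
from semvar.diversity import ContextSet
from semvar.synthetic import sample_directional_clusters
from semvar.variability import (
    ClusterSolution,
    SseProfile,
    between_group_distance,
    cluster_contexts,
    residualize_semvar,
    select_k,
    semantic_variability,
    sse_profile,
    within_group_distance,
)


def profile_of(*sse):
    return SseProfile(k_values=np.arange(1, len(sse) + 1), sse=np.array(sse, float))


def solution_with_centroid_gram(gram):
    cents = np.linalg.cholesky(np.asarray(gram, float))
    k = len(cents)
    return ClusterSolution(
        k=k, assignments=np.arange(k), centroids=cents, sse=0.0
    )


class TestClusterContexts:
    def test_antipodal_duplicates_split_perfectly(self):
        v = np.array([[1.0, 0.0]] * 5 + [[-1.0, 0.0]] * 5)
        sol = cluster_contexts(v, k=2, seed=0)
        assert sol.sse == pytest.approx(0.0, abs=1e-12)
        labels = sol.assignments
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_singleton_clusters_have_zero_sse(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((6, 4))
        sol = cluster_contexts(v, k=6, seed=0)
        assert sol.sse == pytest.approx(0.0, abs=1e-10)

    def test_k_above_n_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            cluster_contexts(np.eye(3), k=4, seed=0)

    def test_zero_vector_is_error(self):
        v = np.vstack([np.eye(3), np.zeros(3)])
        with pytest.raises(ValueError, match="zero-norm"):
            cluster_contexts(v, k=2, seed=0)

    def test_recovers_well_separated_directions(self):
        hits = 0
        for seed in range(50):
            v, labels = sample_directional_clusters(4, 10, d=6, noise=0.1, seed=seed)
            sol = cluster_contexts(v, k=4, seed=seed, n_restarts=10)
            # agreement up to relabeling: each true cluster maps to one label
            ok = all(
                len(set(sol.assignments[labels == c])) == 1 for c in range(4)
            ) and len(set(sol.assignments)) == 4
            hits += ok
        assert hits >= 48  # >= 95% of 50 seeds

    def test_no_empty_clusters_on_duplicated_input(self):
        v = np.array([[1.0, 0.0]] * 7)
        sol = cluster_contexts(v, k=3, seed=0)
        assert len(set(sol.assignments.tolist())) == 3


class TestSseProfile:
    def test_identical_vectors_flat_zero(self):
        v = np.tile([0.6, 0.8], (8, 1))
        prof = sse_profile(v, k_max=5, seed=0, n_restarts=2)
        np.testing.assert_allclose(prof.sse, 0.0, atol=1e-12)

    def test_profile_is_non_increasing(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal((40, 6))
        prof = sse_profile(v, k_max=15, seed=0, n_restarts=3)
        assert np.all(np.diff(prof.sse) <= 1e-12)

    def test_k_max_capped_at_n(self):
        v = np.random.default_rng(0).standard_normal((7, 3))
        prof = sse_profile(v, k_max=50, seed=0, n_restarts=2)
        assert prof.k_values[-1] == 7


class TestSelectK:
    @pytest.mark.parametrize(
        "sse,expected",
        [
            ((100, 10, 5, 2), 2),
            ((100, 60, 30, 12, 8), 4),
            ((50, 50, 50), 1),
        ],
    )
    def test_ninety_percent_reduction_rule(self, sse, expected):
        assert select_k(profile_of(*sse)) == expected

    def test_threshold_parameter(self):
        assert select_k(profile_of(100, 60, 30, 12, 8), threshold=0.5) == 3


class TestGroupDistances:
    def test_singletons_have_zero_within(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((5, 4))
        sol = cluster_contexts(v, k=5, seed=0)
        assert within_group_distance(sol, v) == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_clusters_have_zero_within(self):
        v = np.array([[1.0, 0, 0]] * 4 + [[0, 1.0, 0]] * 4)
        sol = cluster_contexts(v, k=2, seed=0)
        assert within_group_distance(sol, v) == pytest.approx(0.0, abs=1e-12)

    def test_within_matches_per_member_oracle(self):
        rng = np.random.default_rng(2)
        v = np.vstack([
            [1.0, 0.2, 0.1] + 0.3 * rng.standard_normal((6, 3)),
            [-0.9, 0.8, 0.0] + 0.3 * rng.standard_normal((5, 3)),
        ])
        sol = cluster_contexts(v, k=2, seed=0)
        unit = v / np.linalg.norm(v, axis=1)[:, None]
        dists = [
            1.0 - float(np.dot(unit[i], sol.centroids[sol.assignments[i]]))
            for i in range(len(v))
        ]
        assert within_group_distance(sol, v) == pytest.approx(
            float(np.mean(dists)), abs=1e-12
        )

    def test_two_orthogonal_centroids(self):
        sol = solution_with_centroid_gram(np.eye(2))
        assert between_group_distance(sol) == pytest.approx(1.0, abs=1e-12)

    def test_three_orthogonal_centroids(self):
        sol = solution_with_centroid_gram(np.eye(3))
        assert between_group_distance(sol) == pytest.approx(1.0, abs=1e-12)

    def test_centroid_cosines_closed_form(self):
        gram = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.7], [0.8, 0.7, 1.0]])
        sol = solution_with_centroid_gram(gram)
        assert between_group_distance(sol) == pytest.approx(0.2, abs=1e-12)

    def test_between_undefined_below_two_clusters(self):
        sol = ClusterSolution(1, np.zeros(3, int), np.array([[1.0, 0.0]]), 0.0)
        assert between_group_distance(sol) is None


def _cs(n):
    return ContextSet("w0", tuple(f"c{i}" for i in range(n)), (1,) * n, 2000)


class TestSemanticVariability:
    def test_two_tight_antipodal_bundles_score_near_zero(self):
        rng = np.random.default_rng(4)
        a = np.array([1.0, 0, 0]) + 0.01 * rng.standard_normal((15, 3))
        b = np.array([-1.0, 0, 0]) + 0.01 * rng.standard_normal((15, 3))
        v = np.vstack([a, b])
        res = semantic_variability(make_space(v), _cs(30), k_max=10, seed=0, n_restarts=3)
        assert res.semvar is not None
        assert res.semvar < 0.05  # within ~ 0, between ~ 2

    def test_diffuse_cloud_scores_higher_than_split_cloud(self):
        rng = np.random.default_rng(5)
        diffuse = rng.standard_normal((30, 3)) + np.array([2.0, 0, 0])
        a = np.array([1.0, 0, 0]) + 0.05 * rng.standard_normal((15, 3))
        b = np.array([0.0, 1.0, 0]) + 0.05 * rng.standard_normal((15, 3))
        split = np.vstack([a, b])
        kw = dict(k_max=10, seed=0, n_restarts=3)
        hi = semantic_variability(make_space(diffuse), _cs(30), **kw)
        lo = semantic_variability(make_space(split), _cs(30), **kw)
        assert hi.semvar > lo.semvar

    def test_below_min_contexts_is_missing_with_reason(self):
        v = np.random.default_rng(0).standard_normal((5, 3))
        res = semantic_variability(make_space(v), _cs(5), min_contexts=10)
        assert res.semvar is None
        assert res.missing_reason == "insufficient contexts"

    def test_flat_profile_reselects_k_two(self):
        # identical vectors: selection rule returns k=1; a between-group
        # distance needs k >= 2, so the search restarts there
        v = np.tile([0.6, 0.8], (12, 1))
        res = semantic_variability(make_space(v), _cs(12), k_max=5, seed=0, n_restarts=2)
        assert res.k_best == 2
        assert res.k_reselected
        # duplicated points give coincident centroids: between = 0 -> missing
        assert res.missing_reason == "degenerate between-group distance"

    def test_rotation_invariance(self):
        rng = np.random.default_rng(7)
        v, _ = sample_directional_clusters(3, 12, d=8, noise=0.2, seed=3)
        q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        kw = dict(k_max=10, seed=11, n_restarts=3)
        a = semantic_variability(make_space(v), _cs(len(v)), **kw)
        b = semantic_variability(make_space(v @ q), _cs(len(v)), **kw)
        assert b.semvar == pytest.approx(a.semvar, abs=1e-8)


class TestResidualize:
    def test_perfect_fit_gives_zero_residuals(self):
        semvar = {"a": 1.0, "b": 3.0, "c": 5.0}
        log_cd = {"a": 0.0, "b": 1.0, "c": 2.0}
        scores = residualize_semvar(semvar, log_cd)
        assert scores.slope == pytest.approx(2.0, abs=1e-12)
        for r in scores.residuals.values():
            assert r == pytest.approx(0.0, abs=1e-12)

    def test_residuals_orthogonal_to_regressor(self):
        rng = np.random.default_rng(8)
        words = [f"w{i}" for i in range(40)]
        log_cd = {w: float(rng.random() * 3) for w in words}
        semvar = {w: 0.2 + 0.1 * log_cd[w] + float(rng.standard_normal()) * 0.05
                  for w in words}
        scores = residualize_semvar(semvar, log_cd)
        res = np.array([scores.residuals[w] for w in words])
        x = np.array([log_cd[w] for w in words])
        assert abs(res.sum()) < 1e-10
        assert abs(np.corrcoef(res, x)[0, 1]) < 1e-10

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        words = [f"w{i}" for i in range(50)]
        x = rng.random(50) * 2
        y = rng.random(50)
        scores = residualize_semvar(dict(zip(words, y)), dict(zip(words, x)))
        X = np.column_stack([np.ones(50), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        expected = y - X @ beta
        got = np.array([scores.residuals[w] for w in words])
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_missing_semvar_gives_missing_residual(self):
        scores = residualize_semvar(
            {"a": 1.0, "b": 2.0, "c": 3.0, "d": None},
            {"a": 0.0, "b": 1.0, "c": 2.0, "d": 1.5},
        )
        assert scores.residuals["d"] is None

    def test_constant_regressor_is_fatal(self):
        with pytest.raises(ValueError, match="degenerate regressor"):
            residualize_semvar(
                {"a": 1.0, "b": 2.0, "c": 3.0}, {"a": 1.0, "b": 1.0, "c": 1.0}
            )
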