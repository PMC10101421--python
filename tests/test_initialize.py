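import numpy as np
import pytest

from mripem.em import run_em
from mripem.initialize import (default_t, estimate_partition_params,
                               global_mle, min_sq_mahalanobis, mripem_init,
                               mripem_single, partition_by_vectors,
                               select_partition_vector, spherical_fallback,
                               sq_mahalanobis)
from mripem.model import GMMParams, LabeledDataset, log_likelihood
from mripem.simulate import sample_mixture

from conftest import sample_from


def two_cluster_params(distance=20.0, d=2):
    means = np.zeros((2, d))
    means[1, 0] = distance
    return GMMParams(np.array([0.5, 0.5]), means,
                     np.stack([np.eye(d)] * 2))


class TestGlobalMLE:
    def test_two_point_hand_value(self):
        mean, cov = global_mle(np.array([[0.0, 0.0], [2.0, 0.0]]))
        np.testing.assert_allclose(mean, [1.0, 0.0])
        np.testing.assert_allclose(cov, [[1.0, 0.0], [0.0, 0.0]])

    def test_repeated_point_gives_zero_cov(self):
        X = np.tile([[1.5, -2.0]], (6, 1))
        with pytest.raises(ValueError):
            global_mle(X)  # zero variance in every direction

    def test_matches_naive_double_loop(self, rng):
        X = rng.normal(size=(25, 3))
        mean, cov = global_mle(X)
        naive = np.zeros((3, 3))
        for x in X:
            naive += np.outer(x - X.mean(0), x - X.mean(0))
        np.testing.assert_allclose(cov, naive / 25, atol=1e-12)

    def test_divisor_is_n_not_n_minus_one(self, rng):
        X = rng.normal(size=(10, 2))
        _, cov = global_mle(X)
        np.testing.assert_allclose(cov, np.cov(X.T, bias=True), atol=1e-12)


class TestDefaultT:
    @pytest.mark.parametrize("K, expected", [
        (1, 1), (3, 3), (4, 4), (5, 5), (6, 5), (20, 5),
    ])
    def test_rule(self, K, expected):
        assert default_t(K) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            default_t(0)


class TestMahalanobis:
    def test_identity_cov_is_squared_euclidean(self, rng):
        x, mu = rng.normal(size=2), rng.normal(size=2)
        assert sq_mahalanobis(x, mu, np.eye(2)) == pytest.approx(
            ((x - mu) ** 2).sum())

    def test_zero_at_the_mean(self):
        assert sq_mahalanobis([3.0, 4.0], [3.0, 4.0],
                              np.diag([2.0, 5.0])) == pytest.approx(0.0)

    def test_diagonal_scaling(self):
        assert sq_mahalanobis([2.0, 0.0], [0.0, 0.0],
                              np.diag([4.0, 1.0])) == pytest.approx(1.0)

    def test_min_over_centers(self):
        centers = [(np.array([1.0, 0.0]), np.eye(2)),
                   (np.array([0.0, 3.0]), np.eye(2)),
                   (np.array([5.0, 5.0]), np.eye(2))]
        assert min_sq_mahalanobis(np.zeros(2), centers) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            min_sq_mahalanobis(np.zeros(2), [])


class TestSelectPartitionVector:
    def test_single_candidate(self):
        centers = [(np.zeros(2), np.eye(2))]
        point, idx = select_partition_vector(np.array([[0.1, 0.0]]), centers)
        np.testing.assert_allclose(point, [0.1, 0.0])
        assert idx == 0

    def test_farther_candidate_wins(self):
        centers = [(np.zeros(2), np.eye(2))]
        point, idx = select_partition_vector(
            np.array([[1.0, 0.0], [3.0, 0.0]]), centers)
        np.testing.assert_allclose(point, [3.0, 0.0])
        assert idx == 1

    def test_tie_breaks_to_lowest_index(self):
        centers = [(np.zeros(2), np.eye(2))]
        point, idx = select_partition_vector(
            np.array([[2.0, 0.0], [0.0, 2.0]]), centers)
        assert idx == 0


class TestPartitionByVectors:
    def test_single_vector(self, rng):
        labels = partition_by_vectors(rng.normal(size=(7, 2)),
                                      np.zeros((1, 2)))
        np.testing.assert_array_equal(labels, 1)

    def test_nearest_assignment_and_ties(self):
        vectors = np.array([[0.0, 0.0], [10.0, 0.0]])
        X = np.array([[1.0, 0.0], [9.0, 0.0], [5.0, 0.0]])
        np.testing.assert_array_equal(partition_by_vectors(X, vectors),
                                      [1, 2, 1])  # midpoint -> lowest index


class TestSphericalFallback:
    def test_trace_matching_value(self):
        cov = spherical_fallback(np.array([[0.0, 0.0], [2.0, 0.0]]),
                                 np.array([1.0, 0.0]), var_floor=1e-9)
        np.testing.assert_allclose(cov, 0.5 * np.eye(2))

    def test_singleton_hits_floor(self):
        cov = spherical_fallback(np.array([[1.0, 1.0]]), np.array([1.0, 1.0]),
                                 var_floor=1e-4)
        np.testing.assert_allclose(cov, 1e-4 * np.eye(2))

    def test_always_pd(self, rng):
        pts = rng.normal(size=(5, 3))
        cov = spherical_fallback(pts, pts.mean(0), var_floor=1e-8)
        assert np.linalg.eigvalsh(cov).min() > 0


class TestEstimatePartitionParams:
    def test_weights_are_cluster_fractions(self, rng):
        X = rng.normal(size=(4, 2))
        labels = np.array([1, 1, 2, 2])
        p = estimate_partition_params(X, labels)
        np.testing.assert_allclose(p.weights, [0.5, 0.5])

    def test_collinear_cluster_gets_spherical_fallback(self):
        # cluster scatter [[1,0],[0,0]] is singular -> 0.5 I fallback
        X = np.array([[0.0, 0.0], [2.0, 0.0], [10.0, 10.0], [10.0, 11.0],
                      [11.0, 10.0]])
        labels = np.array([1, 1, 2, 2, 2])
        p = estimate_partition_params(X, labels)
        np.testing.assert_allclose(p.covariances[0], 0.5 * np.eye(2))

    def test_true_labels_recover_component_means(self, rng):
        truth = two_cluster_params(distance=10.0)
        data = sample_mixture(truth, 500, rng_seed=5)
        p = estimate_partition_params(data, data.labels)
        order = np.argsort(p.means[:, 0])
        np.testing.assert_allclose(p.means[order], truth.means,
                                   atol=4 / np.sqrt(500))

    def test_empty_cluster_without_prev_means_raises(self, rng):
        X = rng.normal(size=(6, 2))
        labels = np.array([1, 1, 1, 3, 3, 3])  # cluster 2 empty
        with pytest.raises(ValueError, match="empty"):
            estimate_partition_params(X, labels, n_components=3)

    def test_empty_cluster_keeps_previous_mean(self, rng):
        X = rng.normal(size=(6, 2))
        labels = np.array([1, 1, 1, 3, 3, 3])
        prev = np.array([[0.0, 0.0], [50.0, 50.0], [1.0, 1.0]])
        p = estimate_partition_params(X, labels, n_components=3,
                                      prev_means=prev)
        np.testing.assert_allclose(p.means[1], [50.0, 50.0])
        assert p.weights.sum() == pytest.approx(1.0)
        p.validate()


class TestMripemSingle:
    def test_k1_returns_global_mle(self, rng):
        X = rng.normal(size=(40, 2))
        res = mripem_single(X, 1, rng_seed=0)
        mean, cov = global_mle(X)
        np.testing.assert_allclose(res.params.means[0], mean)
        np.testing.assert_allclose(res.params.covariances[0], cov)
        np.testing.assert_array_equal(res.partition, 1)

    def test_postconditions_for_any_k(self, rng):
        X = rng.normal(size=(100, 3)) * [1, 2, 3]
        for K in (2, 4, 7):
            res = mripem_single(X, K, rng_seed=3)
            params = res.params.validate()
            assert params.K == K
            assert res.partition.min() >= 1 and res.partition.max() <= K
            assert params.weights.sum() == pytest.approx(1.0)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(80, 2))
        a = mripem_single(X, 4, rng_seed=11)
        b = mripem_single(X, 4, rng_seed=11)
        np.testing.assert_array_equal(a.partition, b.partition)
        np.testing.assert_array_equal(a.params.means, b.params.means)
        np.testing.assert_array_equal(a.params.covariances,
                                      b.params.covariances)

    def test_finds_both_far_clusters(self):
        """At 20-sigma separation the max-min pick lands in the opposite
        cluster in nearly every seeded run."""
        truth = two_cluster_params(distance=20.0)
        data = sample_mixture(truth, 200, rng_seed=8)
        hits = 0
        for seed in range(100):
            res = mripem_single(data, 2, t=2, rng_seed=seed)
            got = np.sort(res.params.means[:, 0])
            if abs(got[0] - 0.0) < 1.0 and abs(got[1] - 20.0) < 1.0:
                hits += 1
        assert hits >= 95

    def test_rejects_bad_t_and_k(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            mripem_single(X, 2, t=11, rng_seed=0)
        with pytest.raises(ValueError):
            mripem_single(X, 11, rng_seed=0)

    def test_means_spread_beats_random_means(self, rng):
        """The max-min construction places initial means farther apart, on
        average, than uniformly drawn data points."""
        truth = GMMParams(np.full(4, 0.25),
                          np.array([[0., 0.], [8., 0.], [0., 8.], [8., 8.]]),
                          np.stack([np.eye(2)] * 4))
        data = sample_mixture(truth, 100, rng_seed=2)

        def min_pairwise(M):
            d2 = ((M[:, None] - M[None]) ** 2).sum(-1)
            return np.sqrt(d2[np.triu_indices(len(M), 1)].min())

        ours, rand = [], []
        for seed in range(50):
            res = mripem_single(data, 4, rng_seed=seed)
            ours.append(min_pairwise(res.params.means))
            pick = np.random.default_rng(seed).choice(data.n, 4, replace=False)
            rand.append(min_pairwise(data.X[pick]))
        assert np.mean(ours) >= np.mean(rand)


class TestMripemInit:
    def test_r1_equals_single_run(self, rng):
        truth = two_cluster_params()
        data = sample_mixture(truth, 50, rng_seed=1)
        multi = mripem_init(data, 2, r=1, rng_seed=5)
        single = mripem_single(data, 2, rng_seed=5)
        np.testing.assert_array_equal(multi.params.means, single.params.means)
        np.testing.assert_array_equal(multi.partition, single.partition)

    def test_selection_score_is_max_over_restarts(self):
        truth = two_cluster_params()
        data = sample_mixture(truth, 50, rng_seed=1)
        from mripem.metrics import adjusted_rand_index
        scores = [adjusted_rand_index(
            data.labels, mripem_single(data, 2, rng_seed=5 + j).partition)
            for j in range(6)]
        best = mripem_init(data, 2, r=6, rng_seed=5, criterion="ari")
        assert best.selection_score == pytest.approx(max(scores))

    def test_ari_criterion_requires_labels(self, rng):
        X = rng.normal(size=(30, 2))
        with pytest.raises(ValueError, match="loglik"):
            mripem_init(X, 2, criterion="ari")

    def test_loglik_criterion_without_labels(self, rng):
        X = np.r_[rng.normal(size=(30, 2)), rng.normal(size=(30, 2)) + 8]
        res = mripem_init(X, 2, r=3, rng_seed=0)
        assert res.criterion == "loglik"
        assert res.selection_score == pytest.approx(
            log_likelihood(LabeledDataset(X), res.params))

    def test_em_from_init_never_degrades_loglik(self, rng):
        truth = two_cluster_params(distance=6.0)
        data = sample_mixture(truth, 100, rng_seed=3)
        init = mripem_init(data, 2, r=4, rng_seed=9)
        res = run_em(data, init.params)
        assert res.final_loglik >= log_likelihood(data, init.params) - 1e-8
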