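import numpy as np
import pytest

from pkmeans import (
    DegenerateModelError,
    estep_allocate,
    kmeanspp_init,
    mstep_update,
    multi_restart_fit,
    penalized_kmeans_fit,
)
from pkmeans.core import model_score

from conftest import make_matrix


def two_blobs_1d(rng, n=40):
    """n points split between two well-separated 1-D blobs at -5 and +5."""
    x = np.concatenate([rng.normal(-5, 0.3, n // 2), rng.normal(5, 0.3, n // 2)])
    return x[:, None]


class TestKmeansppInit:
    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((50, 3))
        a = kmeanspp_init(X, 5, rng_seed=7)
        b = kmeanspp_init(X, 5, rng_seed=7)
        np.testing.assert_array_equal(a, b)

    def test_centers_are_data_points(self, rng):
        X = rng.standard_normal((30, 2))
        centers = kmeanspp_init(X, 4, rng_seed=0)
        for c in centers:
            assert np.any(np.all(X == c, axis=1))

    def test_k_equals_n_yields_every_point(self, rng):
        # D^2 weighting gives zero mass to chosen points, so all n distinct
        # points must appear exactly once
        X = rng.standard_normal((8, 2))
        centers = kmeanspp_init(X, 8, rng_seed=3)
        assert centers.shape == (8, 2)
        sorted_x = X[np.lexsort(X.T)]
        sorted_c = centers[np.lexsort(centers.T)]
        np.testing.assert_array_equal(sorted_x, sorted_c)

    def test_duplicate_points_fall_back_gracefully(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        centers = kmeanspp_init(X, 4, rng_seed=0)
        assert centers.shape == (4, 1)

    @pytest.mark.parametrize("k", [0, 9])
    def test_invalid_k(self, rng, k):
        with pytest.raises(ValueError):
            kmeanspp_init(rng.standard_normal((8, 2)), k, rng_seed=0)


class TestEStep:
    def test_nearest_center_wins(self):
        part = estep_allocate(np.array([[4.0]]), np.array([[0.0], [10.0]]))
        assert part.labels[0] == 0

    def test_tie_breaks_to_lowest_index(self):
        part = estep_allocate(np.array([[5.0]]), np.array([[0.0], [10.0]]))
        assert part.labels[0] == 0

    def test_single_center_takes_all(self, rng):
        X = rng.standard_normal((20, 2))
        part = estep_allocate(X, np.zeros((1, 2)))
        assert np.all(part.labels == 0)

    def test_empty_center_set_rejected(self, rng):
        with pytest.raises(ValueError):
            estep_allocate(rng.standard_normal((5, 2)), np.empty((0, 2)))


class TestMStep:
    def test_zero_penalty_is_plain_mean(self):
        X = np.array([[0.0], [2.0]])
        centers = mstep_update(X, np.array([0, 0]), lam=0.0, n_centers=1)
        assert centers[0, 0] == 1.0

    def test_soft_threshold_eliminates(self):
        # two members at 1, lam 8: max(1 - 8/(2*2), 0) = 0
        X = np.array([[1.0], [1.0]])
        centers = mstep_update(X, np.array([0, 0]), lam=8.0, n_centers=1)
        assert centers[0, 0] == 0.0

    def test_soft_threshold_negative_mean(self):
        # four members with mean -3, lam 8: -(3 - 8/(2*4)) = -2
        X = np.array([[-3.0], [-4.0], [-2.0], [-3.0]])
        centers = mstep_update(X, np.zeros(4, dtype=int), lam=8.0, n_centers=1)
        assert centers[0, 0] == -2.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            mstep_update(np.array([[1.0], [2.0]]), np.array([0, 1]), lam=-1.0)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mstep_update(np.array([[1.0], [2.0]]), np.array([0, 0]), lam=0.0, n_centers=2)

    @pytest.mark.parametrize("lam", [0.0, 0.5, 2.0, 10.0])
    def test_update_minimizes_objective(self, rng, lam):
        # per cluster and coordinate, the soft-threshold update must beat a
        # dense grid of candidate center positions around the member mean
        x = rng.normal(2.0, 1.0, 25)
        labels = np.zeros(25, dtype=int)
        mu = mstep_update(x[:, None], labels, lam=lam, n_centers=1)[0, 0]
        grid = np.linspace(x.mean() - 3, x.mean() + 3, 2001)
        q = ((x[:, None] - grid[None, :]) ** 2).sum(axis=0) + lam * np.abs(grid)
        q_mu = ((x - mu) ** 2).sum() + lam * abs(mu)
        assert q_mu <= q.min() + 1e-9

    def test_sparsity_monotone_in_lambda(self, rng):
        # at fixed allocation the non-zero support shrinks as lam grows
        X = rng.standard_normal((60, 4)) * 0.3
        labels = rng.integers(0, 3, 60)
        prev = np.inf
        for lam in [0.0, 1.0, 4.0, 16.0, 64.0]:
            nz = int(np.count_nonzero(mstep_update(X, labels, lam, n_centers=3)))
            assert nz <= prev
            prev = nz


class TestPenalizedFit:
    def test_zero_penalty_matches_reference_kmeans(self, rng):
        # lam=0 reduces to plain k-means: same init must give the same
        # partition as sklearn's Lloyd iteration
        sklearn = pytest.importorskip("sklearn.cluster")
        X = rng.standard_normal((120, 3))
        init = kmeanspp_init(X, 4, rng_seed=5)
        model, part = penalized_kmeans_fit(X, 4, 0.0, rng_seed=5, init_centers=init)
        ref = sklearn.KMeans(n_clusters=4, init=init, n_init=1, tol=0, max_iter=300,
                             algorithm="lloyd").fit(X)
        from pkmeans import ari_exact

        assert ari_exact(part.labels, ref.labels_) == 1.0

    def test_two_blobs_collapse_to_two_clusters(self, rng):
        X = two_blobs_1d(rng)
        model, part = penalized_kmeans_fit(X, 5, lam=20.0, rng_seed=0)
        assert model.n_clusters == 2
        assert part.n_clusters == 2
        assert sorted(np.sign(model.centers[:, 0])) == [-1.0, 1.0]

    def test_huge_penalty_degenerates(self, rng):
        X = rng.standard_normal((30, 2))
        with pytest.raises(DegenerateModelError):
            penalized_kmeans_fit(X, 3, lam=1e9, rng_seed=0)

    def test_score_is_reconstructible(self, rng):
        X = two_blobs_1d(rng)
        model, part = penalized_kmeans_fit(X, 5, lam=3.0, rng_seed=1)
        q = model_score(X, part.labels, model.centers, model.penalty)
        assert abs(q - model.score) <= 1e-6 * max(1.0, abs(model.score))

    def test_no_all_zero_center_rows(self, rng):
        X = two_blobs_1d(rng)
        model, _ = penalized_kmeans_fit(X, 5, lam=10.0, rng_seed=2)
        assert np.all(np.any(model.centers != 0, axis=1))

    def test_k_below_two_rejected(self, rng):
        with pytest.raises(ValueError):
            penalized_kmeans_fit(rng.standard_normal((10, 2)), 1, 0.0, rng_seed=0)

    def test_score_descends_over_em_pairs(self, rng):
        # with the effective penalty held at its final value, each E+M pair
        # must not increase Q; verified by stepping manually
        X = rng.standard_normal((80, 3))
        lam = 2.0
        centers = kmeanspp_init(X, 6, rng_seed=9)
        prev_q = np.inf
        for _ in range(20):
            part = estep_allocate(X, centers)
            counts = np.bincount(part.labels, minlength=centers.shape[0])
            keep = counts > 0
            centers = centers[keep]
            labels = np.cumsum(keep)[part.labels] - 1
            centers = mstep_update(X, labels, lam, centers.shape[0])
            alive = np.any(centers != 0, axis=1)
            centers = centers[alive]
            labels2 = estep_allocate(X, centers).labels
            q = model_score(X, labels2, centers, lam)
            assert q <= prev_q + 1e-8
            prev_q = q


class TestMultiRestart:
    def test_single_run_equals_direct_fit(self, rng):
        X = two_blobs_1d(rng)
        m1, p1 = multi_restart_fit(X, 4, 1.0, n_runs=1, base_seed=11)
        m2, p2 = penalized_kmeans_fit(X, 4, 1.0, rng_seed=11)
        np.testing.assert_array_equal(m1.centers, m2.centers)
        np.testing.assert_array_equal(p1.labels, p2.labels)

    def test_returns_minimum_score(self, rng):
        X = two_blobs_1d(rng, n=60)
        best, _ = multi_restart_fit(X, 4, 1.0, n_runs=5, base_seed=0)
        for r in range(5):
            m, _ = penalized_kmeans_fit(X, 4, 1.0, rng_seed=r)
            assert best.score <= m.score + 1e-12

    def test_deterministic(self, rng):
        X = two_blobs_1d(rng)
        a, _ = multi_restart_fit(X, 4, 2.0, n_runs=3, base_seed=1)
        b, _ = multi_restart_fit(X, 4, 2.0, n_runs=3, base_seed=1)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_all_degenerate_raises(self, rng):
        X = rng.standard_normal((20, 2))
        with pytest.raises(DegenerateModelError):
            multi_restart_fit(X, 3, 1e9, n_runs=3, base_seed=0)

    def test_invalid_n_runs(self, rng):
        with pytest.raises(ValueError):
            multi_restart_fit(rng.standard_normal((10, 2)), 2, 0.0, n_runs=0)


class TestSoftThresholdProperties:
    """Algebraic invariants of the penalized center update."""

    from hypothesis import given, settings, strategies as st

    members = st.lists(
        st.floats(-50, 50, allow_nan=False), min_size=1, max_size=20
    )

    @given(xs=members, lam=st.floats(0, 100))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_shrinks_toward_zero_without_crossing(self, xs, lam):
        x = np.array(xs)[:, None]
        mu = mstep_update(x, np.zeros(len(xs), dtype=int), lam, n_centers=1)[0, 0]
        mean = x.mean()
        assert abs(mu) <= abs(mean) + 1e-12
        assert mu * mean >= 0  # never crosses zero
        # exact zero iff the member mean is inside the threshold
        if abs(mean) <= lam / (2 * len(xs)):
            assert mu == 0.0
        else:
            assert mu != 0.0
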