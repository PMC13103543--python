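import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from conftest import make_window_series
from dfcstates.cluster import (
    assign_states,
    best_of_replicates,
    elbow_curve,
    elbow_knee,
    exemplar_windows,
    kmeans_two_stage,
    lloyd,
    relabel_model,
    reporting_order,
)
from dfcstates.types import StateModel


def series_with_variances(variances):
    """Window series whose across-edge population variance is as given (E=3)."""
    rows = [[np.sqrt(3 * v / 2), 0.0, -np.sqrt(3 * v / 2)] for v in variances]
    return make_window_series(np.array(rows))


class TestExemplars:
    def test_strict_local_maxima(self):
        idx = exemplar_windows(series_with_variances([1, 3, 2, 5, 4]))
        np.testing.assert_array_equal(idx, [1, 3])  # 0-based positions 2,4 (1-based)

    def test_monotone_falls_back_to_argmax(self):
        idx = exemplar_windows(series_with_variances([1, 2, 3, 4, 5]))
        np.testing.assert_array_equal(idx, [4])

    def test_constant_falls_back_to_first(self):
        idx = exemplar_windows(series_with_variances([2, 2, 2, 2]))
        np.testing.assert_array_equal(idx, [0])

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match=">= 3 valid windows"):
            exemplar_windows(series_with_variances([1, 2]))


def blobs(rng, k=3, n_per=200, dim=10, sep=10.0):
    centers = rng.standard_normal((k, dim)) * sep
    X = np.vstack([centers[i] + rng.standard_normal((n_per, dim)) for i in range(k)])
    labels = np.repeat(np.arange(k), n_per)
    return X, labels


class TestKMeans:
    def test_k1_closed_form(self, rng):
        X = rng.standard_normal((50, 4))
        model = kmeans_two_stage(X, X, k=1, replicates=3, seed=0)
        np.testing.assert_allclose(model.centroids[0], X.mean(axis=0), atol=1e-12)
        assert model.wcss == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    def test_well_separated_blobs_ari_1(self, rng):
        X, planted = blobs(rng)
        model = kmeans_two_stage(X, X, k=3, replicates=10, seed=1)
        labels, _ = _assign_labels(X, model)
        assert adjusted_rand_score(planted, labels) == 1.0

    def test_agrees_with_sklearn_on_blobs(self, rng):
        """Independent oracle: same partition as scikit-learn's k-means."""
        X, _ = blobs(rng, sep=6.0)
        model = kmeans_two_stage(X, X, k=3, replicates=10, seed=2)
        sk = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        ours, _ = _assign_labels(X, model)
        assert adjusted_rand_score(sk.labels_, ours) == 1.0
        assert model.wcss == pytest.approx(sk.inertia_, rel=1e-9)

    def test_stage2_never_worse_than_stage1_centroids(self, rng):
        X, _ = blobs(rng, sep=1.0)
        exemplars = X[::5]
        c1, _, _ = best_of_replicates(exemplars, 3, 10, 100, seed=3)
        _, d2 = _assign_dist(X, c1)
        wcss_stage1 = d2.min(axis=1).sum()
        model = kmeans_two_stage(exemplars, X, 3, replicates=10, seed=3)
        assert model.wcss <= wcss_stage1 + 1e-9

    def test_deterministic_given_seed(self, rng):
        X, _ = blobs(rng, sep=1.5)
        m1 = kmeans_two_stage(X[::3], X, 3, replicates=5, seed=9)
        m2 = kmeans_two_stage(X[::3], X, 3, replicates=5, seed=9)
        np.testing.assert_array_equal(m1.centroids, m2.centroids)
        assert m1.wcss == m2.wcss

    def test_best_wcss_nonincreasing_in_replicates(self, rng):
        X = rng.standard_normal((120, 5))
        wcss = [
            best_of_replicates(X, 4, r, 100, seed=11)[2] for r in (1, 3, 10, 30)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(wcss, wcss[1:]))

    def test_infeasible_k(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.raises(ValueError, match="infeasible"):
            kmeans_two_stage(X[:2], X, k=3, replicates=2, seed=0)

    def test_empty_cluster_reseeded(self):
        # both initial centroids tie to the same points; one goes empty
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        init = np.array([[0.05], [100.0]])
        centroids, labels, _ = lloyd(X, init, max_iter=50)
        assert len(np.unique(labels)) == 2


def _assign_dist(X, centroids):
    d2 = ((X[:, None, :] - centroids[None]) ** 2).sum(-1)
    return d2.argmin(1), d2


def _assign_labels(X, model):
    return _assign_dist(X, model.centroids)


class TestElbow:
    def test_knee_at_three_planted_blobs(self, rng):
        X, _ = blobs(rng, k=3, n_per=150, dim=8, sep=8.0)
        curve = elbow_curve(X, (1, 6), replicates=5, seed=4)
        wcss = np.array([w for _, w in curve])
        assert np.all(np.diff(wcss) <= 1e-9)  # monotone in k
        assert elbow_knee(curve) == 3

    def test_wcss_zero_at_k_equals_distinct_points(self):
        X = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        curve = elbow_curve(X, (1, 4), replicates=5, seed=5)
        assert curve[-1][1] == pytest.approx(0.0, abs=1e-12)


class TestAssignment:
    def test_window_equal_to_centroid(self, rng):
        centroids = rng.standard_normal((3, 6))
        model = _model(centroids)
        series = make_window_series(np.vstack([centroids[1], centroids[2], centroids[0]]))
        seq = assign_states(series, model)
        np.testing.assert_array_equal(seq.labels, [2, 3, 1])

    def test_equidistant_tie_breaks_to_lowest_state(self):
        # the point (1,0,0) is equidistant from centroids 1 and 2
        centroids = np.array([[0.0, 0, 0], [2, 0, 0], [1, 5, 5]])
        series = make_window_series(np.array([[1.0, 0.0, 0.0]]))
        seq = assign_states(series, _model(centroids))
        assert seq.labels[0] == 1

    def test_invalid_windows_omitted(self, rng):
        edges = rng.standard_normal((5, 3))
        series = make_window_series(edges, valid=[1, 0, 1, 0, 1])
        seq = assign_states(series, _model(rng.standard_normal((2, 3))))
        np.testing.assert_array_equal(seq.window_indices, [0, 2, 4])

    def test_dimension_mismatch(self, rng):
        series = make_window_series(rng.standard_normal((4, 6)))
        with pytest.raises(ValueError, match="E="):
            assign_states(series, _model(rng.standard_normal((2, 3))))

    def test_training_assignment_reproduces_partition(self, rng):
        X, _ = blobs(rng, sep=2.0, dim=3)
        model = kmeans_two_stage(X[::4], X, 3, replicates=5, seed=6)
        labels, _ = _assign_labels(X, model)
        # one more Lloyd sweep does not move the centroids
        recomputed = np.vstack([X[labels == j].mean(axis=0) for j in range(3)])
        np.testing.assert_allclose(recomputed, model.centroids, atol=1e-8)


def _model(centroids):
    return StateModel(
        k=centroids.shape[0], centroids=centroids, wcss=0.0, seed=0,
        replicates=1, stage1_exemplar_count=centroids.shape[0],
    )


class TestReportingConvention:
    def test_ascending_means_map_to_2_1_3(self):
        # centroid means: row0=0.5 (highest), row1=0.1 (lowest), row2=0.3
        centroids = np.array([[0.5] * 3, [0.1] * 3, [0.3] * 3])
        model = _model(centroids)
        # lowest mean -> reported state 2, middle -> 1, highest -> 3
        np.testing.assert_array_equal(reporting_order(model), [3, 2, 1])
        relabeled = relabel_model(model)
        means = relabeled.centroids.mean(axis=1)
        assert means[1] == pytest.approx(0.1)  # state 2 hypoconnected
        assert means[0] == pytest.approx(0.3)  # state 1 moderate
        assert means[2] == pytest.approx(0.5)  # state 3 hyperconnected
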