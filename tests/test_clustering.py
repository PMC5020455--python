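"""Ward seeding, K-means consolidation and Calinski-Harabasz selection."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import calinski_harabasz_score

import smsfreq as sf


def gaussian_clouds(rng, centers, n_per=20, spread=0.1):
    """Archetype-like point clouds with controllable separation."""
    centers = np.asarray(centers, float)
    pts = np.concatenate(
        [c + spread * rng.standard_normal((n_per, centers.shape[1])) for c in centers]
    )
    truth = np.repeat(np.arange(1, len(centers) + 1), n_per)
    return pts, truth


def naive_ward(matrix, k):
    """O(n^3) reference Ward: repeatedly merge the pair of clusters whose
    union least increases the total within-cluster sum of squares."""
    clusters = [[i] for i in range(len(matrix))]
    heights = []
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pa, pb = matrix[clusters[a]], matrix[clusters[b]]
                merged = np.vstack([pa, pb])
                d = (
                    ((merged - merged.mean(0)) ** 2).sum()
                    - ((pa - pa.mean(0)) ** 2).sum()
                    - ((pb - pb.mean(0)) ** 2).sum()
                )
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(matrix), dtype=int)
    for j, members in enumerate(clusters, start=1):
        labels[members] = j
    return labels, heights


def partitions_equal(a, b):
    from sklearn.metrics import adjusted_rand_score

    return adjusted_rand_score(a, b) == pytest.approx(1.0)


class TestWard:
    def test_k_equals_n_gives_singletons(self, rng):
        pts = rng.standard_normal((6, 2))
        labels = sf.ward_cluster(pts, 6)
        assert len(np.unique(labels)) == 6

    def test_two_separated_clouds_recovered(self, rng):
        pts, truth = gaussian_clouds(rng, [[0, 0], [100, 100]], spread=1.0)
        assert partitions_equal(sf.ward_cluster(pts, 2), truth)

    def test_matches_naive_ward_and_heights_monotone(self, rng):
        """scipy's Ward agrees with a naive minimum-variance merger on
        small random data, and merge costs never decrease."""
        from scipy.cluster.hierarchy import linkage

        for n in (8, 12, 20):
            pts = rng.standard_normal((n, 3))
            Z = linkage(pts, method="ward")
            assert np.all(np.diff(Z[:, 2]) >= -1e-9)
            for k in (2, 3, 4):
                naive_labels, _ = naive_ward(pts, k)
                assert partitions_equal(sf.ward_cluster(pts, k), naive_labels)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            sf.ward_cluster(rng.standard_normal((4, 2)), 5)


class TestKMeans:
    def test_local_optimum_is_fixed_point(self, rng):
        pts, truth = gaussian_clouds(rng, [[0, 0], [50, 50]], spread=0.5)
        np.testing.assert_array_equal(sf.kmeans_consolidate(pts, truth), truth)

    def test_wcss_never_increases_from_ward_init(self, rng):
        def wcss(pts, labels):
            return sum(
                ((pts[labels == j] - pts[labels == j].mean(0)) ** 2).sum()
                for j in np.unique(labels)
            )

        for _ in range(5):
            pts = rng.standard_normal((40, 4))
            init = sf.ward_cluster(pts, 4)
            out = sf.kmeans_consolidate(pts, init)
            assert wcss(pts, out) <= wcss(pts, init) + 1e-9

    def test_final_labels_are_nearest_centroid_assignment(self, rng):
        pts = rng.standard_normal((50, 3))
        labels = sf.kmeans_consolidate(pts, sf.ward_cluster(pts, 5))
        centroids = np.stack([pts[labels == j].mean(0) for j in range(1, 6)])
        brute = cdist(pts, centroids).argmin(axis=1) + 1
        np.testing.assert_array_equal(labels, brute)

    def test_k_is_preserved(self, rng):
        pts = rng.standard_normal((30, 2))
        out = sf.kmeans_consolidate(pts, sf.ward_cluster(pts, 6))
        assert set(np.unique(out)) == set(range(1, 7))


class TestCalinskiHarabasz:
    def test_hand_computed_six_point_fixture(self):
        """Points 0,1,2 | 10,11,12 on a line: SSB=150, SSW=4, k=2, n=6
        -> (150/1)/(4/4) = 150."""
        pts = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        labels = np.array([1, 1, 1, 2, 2, 2])
        assert sf.calinski_harabasz(pts, labels) == pytest.approx(150.0)

    def test_anova_decomposition(self, rng):
        pts = rng.standard_normal((30, 4))
        labels = rng.integers(1, 4, size=30)
        labels[:3] = [1, 2, 3]
        total = ((pts - pts.mean(0)) ** 2).sum()
        ss_b = sum(
            (labels == j).sum() * ((pts[labels == j].mean(0) - pts.mean(0)) ** 2).sum()
            for j in np.unique(labels)
        )
        ss_w = sum(
            ((pts[labels == j] - pts[labels == j].mean(0)) ** 2).sum()
            for j in np.unique(labels)
        )
        assert total == pytest.approx(ss_b + ss_w, abs=1e-9)
        k, n = 3, 30
        assert sf.calinski_harabasz(pts, labels) == pytest.approx(
            (ss_b / (k - 1)) / (ss_w / (n - k))
        )

    def test_agrees_with_sklearn(self, rng):
        pts = rng.standard_normal((40, 3))
        labels = sf.ward_cluster(pts, 4)
        assert sf.calinski_harabasz(pts, labels) == pytest.approx(
            calinski_harabasz_score(pts, labels)
        )

    def test_duplicating_points_recomputes_consistently(self, rng):
        pts = rng.standard_normal((12, 2))
        labels = sf.ward_cluster(pts, 3)
        doubled = np.vstack([pts, pts])
        dlabels = np.concatenate([labels, labels])
        n, k = 12, 3
        ratio_single = sf.calinski_harabasz(pts, labels) / ((n - k) / (k - 1))
        ratio_double = sf.calinski_harabasz(doubled, dlabels) / ((2 * n - k) / (k - 1))
        # centroids unchanged => SSB/SSW ratio doubles with the counts
        assert ratio_double == pytest.approx(ratio_single)

    @pytest.mark.parametrize("k", [1, 6])
    def test_degenerate_k_rejected(self, rng, k):
        pts = rng.standard_normal((6, 2))
        with pytest.raises(ValueError):
            sf.calinski_harabasz(pts, np.arange(6) % k + 1 if k > 1 else np.ones(6, int))


class TestOptimalK:
    def test_four_separated_clouds_give_k4(self, rng):
        """Four archetype-like clouds at >=10x their internal spread."""
        pts, truth = gaussian_clouds(
            rng, [[0, 0, 0, 0], [5, 0, 0, 0], [0, 5, 0, 0], [0, 0, 5, 0]], spread=0.3
        )
        best, profile = sf.optimal_k(pts)
        assert best.k == 4
        assert partitions_equal(best.labels, truth)
        assert sorted(profile) == list(range(2, 9))

    def test_two_blobs_give_k2(self, rng):
        pts, _ = gaussian_clouds(rng, [[0, 0], [30, 30]], spread=0.5)
        best, _ = sf.optimal_k(pts, k_max=6)
        assert best.k == 2

    def test_profile_covers_requested_range(self, rng):
        pts = rng.standard_normal((25, 3))
        _, profile = sf.optimal_k(pts, k_min=2, k_max=5)
        assert sorted(profile) == [2, 3, 4, 5]

    def test_stage_is_deterministic(self, noise_free_cohort):
        fits = sf.fit_cohort(noise_free_cohort)
        mat = sf.parameter_matrix(fits)
        b1, p1 = sf.optimal_k(mat)
        b2, p2 = sf.optimal_k(mat)
        np.testing.assert_array_equal(b1.labels, b2.labels)
        assert p1 == p2
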