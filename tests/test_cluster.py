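"""Clustering core: k approximation, HK-means, census and flag rule."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from labsieve import (
    approximate_k,
    cluster_census,
    flag_sparse,
    flag_threshold,
    hierarchical_centroids,
    hkmeans,
    kmeans_refine,
)
from labsieve.cluster import ClusterModel

from .oracles import dp_optimal_wss, exhaustive_optimal_wss, silhouette_best_k


class TestApproximateK:
    def test_three_tight_gaussians(self, rng):
        x = np.concatenate(
            [rng.normal(c, 0.5, 100) for c in (0.0, 50.0, 100.0)]
        )
        assert silhouette_best_k(x, range(2, 11)) == 3  # oracle agrees
        assert approximate_k(x, k_max=10, seed=1) == 3

    def test_identical_points_give_one_cluster(self):
        assert approximate_k(np.full(100, 7.0), k_max=10, seed=0) == 1

    def test_single_gaussian_stays_small(self, rng):
        x = rng.normal(0, 1, 200)
        assert approximate_k(x, k_max=10, seed=2) <= 3

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(0, 1, 3000)
        ks = {approximate_k(x, k_max=8, seed=5) for _ in range(3)}
        assert len(ks) == 1

    @pytest.mark.parametrize("a,b", [(2.5, 0.0), (0.001, 7.0), (-3.0, 1.0)])
    def test_affine_equivariance(self, rng, a, b):
        x = np.concatenate([rng.normal(0, 1, 150), rng.normal(30, 1, 150)])
        assert approximate_k(x, 8, seed=3) == approximate_k(a * x + b, 8, seed=3)

    def test_agrees_with_sklearn_gmm_bic_on_separated_data(self, rng):
        # independent mixture-model route: sklearn's GaussianMixture BIC
        from sklearn.mixture import GaussianMixture

        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(40, 1, 200)])
        bics = [
            GaussianMixture(k, n_init=3, random_state=0)
            .fit(x.reshape(-1, 1))
            .bic(x.reshape(-1, 1))
            for k in range(1, 6)
        ]
        assert int(np.argmin(bics)) + 1 == approximate_k(x, 5, seed=4) == 2


class TestHierarchicalCentroids:
    def test_two_well_separated_pairs(self):
        cents = hierarchical_centroids([0.0, 1.0, 10.0, 11.0], 2)
        np.testing.assert_allclose(np.sort(cents), [0.5, 10.5])

    def test_k_one_gives_global_mean(self, rng):
        x = rng.normal(5, 2, 40)
        np.testing.assert_allclose(hierarchical_centroids(x, 1), [x.mean()])

    def test_repeated_values_isolate_outlier(self):
        cents = hierarchical_centroids([0.0, 0.0, 0.0, 9.0], 2)
        np.testing.assert_allclose(np.sort(cents), [0.0, 9.0])

    def test_k_above_distinct_count_is_reduced(self):
        with pytest.warns(UserWarning, match="distinct"):
            cents = hierarchical_centroids([1.0, 1.0, 2.0], 3)
        assert cents.size == 2


class TestKmeansRefine:
    def test_hand_worked_example(self):
        model = kmeans_refine([0.0, 1.0, 10.0, 11.0], [0.5, 10.5])
        np.testing.assert_array_equal(model.assignments, [0, 0, 1, 1])
        assert model.distortion == pytest.approx(1.0)
        assert model.distortion == pytest.approx(
            exhaustive_optimal_wss([0.0, 1.0, 10.0, 11.0], 2)
        )

    def test_one_centroid_per_point_gives_zero_distortion(self):
        x = [3.0, 1.0, 2.0]
        model = kmeans_refine(x, x)
        assert model.distortion == 0.0
        assert model.k == 3

    def test_refining_a_converged_model_is_a_fixed_point(self, rng):
        x = rng.normal(0, 1, 60)
        m1 = kmeans_refine(x, [-1.0, 1.0])
        m2 = kmeans_refine(x, m1.centroids)
        np.testing.assert_array_equal(m1.assignments, m2.assignments)
        np.testing.assert_allclose(m1.centroids, m2.centroids)

    def test_distortion_monotone_non_increasing(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 200))
            k = int(rng.integers(1, 6))
            x = rng.normal(0, 10, n)
            init = rng.choice(x, size=min(k, n), replace=False)
            model = kmeans_refine(x, init)
            hist = np.array(model.distortion_history)
            assert np.all(np.diff(hist) <= 1e-9)

    def test_empty_clusters_dropped(self):
        # far-away duplicate centroid can never win a point
        model = kmeans_refine([0.0, 0.1, 0.2], [0.1, 500.0])
        assert model.k == 1
        assert model.populations.tolist() == [3]

    def test_populations_sum_to_n(self, rng):
        x = rng.normal(0, 1, 50)
        model = kmeans_refine(x, [-1.0, 0.0, 1.0])
        assert model.populations.sum() == 50
        assert all(p >= 1 for p in model.populations)


class TestHkmeans:
    def test_two_pair_partition(self):
        model = hkmeans([0.0, 1.0, 10.0, 11.0], 2)
        groups = {tuple(np.flatnonzero(model.assignments == j))
                  for j in range(model.k)}
        assert groups == {(0, 1), (2, 3)}

    def test_refinement_never_worse_than_hierarchical_cut(self, rng):
        from scipy.cluster.hierarchy import fcluster, linkage

        for _ in range(20):
            x = rng.normal(0, 5, 20)
            g = fcluster(linkage(x[:, None], "ward"), 4, criterion="maxclust")
            cut_wss = sum(
                ((x[g == j] - x[g == j].mean()) ** 2).sum()
                for j in np.unique(g)
            )
            assert hkmeans(x, 4).distortion <= cut_wss + 1e-9

    def test_clusters_are_contiguous_in_sorted_order(self, rng):
        x = np.sort(rng.lognormal(1, 1, 50))
        model = hkmeans(x, 4)
        # cluster label changes at most k-1 times along the sorted axis
        changes = np.sum(np.diff(model.assignments) != 0)
        assert changes == model.k - 1

    def test_near_optimality_battery_against_dp_oracle(self):
        # Ward+Lloyd is a heuristic: on a fixed battery of 1-D instances it
        # is never below the DP optimum and lands on it in most cases.
        rng = np.random.default_rng(7)
        ratios = []
        n_optimal = 0
        total = 0
        for trial in range(100):
            n = int(rng.integers(20, 51))
            k = int(rng.integers(2, 6))
            kind = trial % 3
            if kind == 0:
                x = rng.normal(0, 10, n)
            elif kind == 1:
                x = rng.lognormal(1, 1, n)
            else:
                x = np.concatenate(
                    [rng.normal(0, 1, n - 2), [50.0, 120.0]]
                )
            if np.unique(x).size <= k:
                continue
            total += 1
            model = hkmeans(x, k)
            opt = dp_optimal_wss(x, model.k)
            assert model.distortion >= opt - 1e-9
            ratio = opt / model.distortion if model.distortion > 0 else 1.0
            ratios.append(ratio)
            n_optimal += ratio > 1 - 1e-9
        assert np.mean(ratios) >= 0.95
        assert n_optimal / total >= 0.5

    def test_deterministic_on_large_input(self, rng):
        x = rng.lognormal(3, 1, 5000)
        m1, m2 = hkmeans(x, 3, seed=11), hkmeans(x, 3, seed=11)
        np.testing.assert_array_equal(m1.assignments, m2.assignments)


class TestCensusAndFlagRule:
    def test_census_counts(self):
        model = kmeans_refine([0.0, 0.1, 10.0], [0.05, 10.0])
        assert cluster_census(model) == [(0, 2), (1, 1)]

    def test_census_sums_to_n(self, rng):
        x = rng.normal(0, 1, 200)
        model = hkmeans(x, 4)
        assert sum(p for _, p in cluster_census(model)) == 200

    @pytest.mark.parametrize(
        "fold_length,alpha,expected",
        [
            (10_000, 1 / 10_000, 1),
            (500, 1 / 500, 1),
            (10_000, 1 / 500, 20),
            (1000, 1 / 1000, 1),
            (3000, 1 / 3000, 1),
            (6000, 1 / 6000, 1),
            (499, 1 / 500, 0),
            (10, 1.0, 10),
        ],
    )
    def test_flag_threshold(self, fold_length, alpha, expected):
        assert flag_threshold(fold_length, alpha) == expected

    def test_flag_threshold_rejects_bad_alpha(self):
        with pytest.raises(ValueError):
            flag_threshold(100, 0.0)

    def test_singleton_cluster_flagged_at_threshold_one(self):
        model = ClusterModel(
            k=2,
            centroids=np.array([0.0, 99.0]),
            assignments=np.array([0] * 9999 + [1]),
            populations=np.array([9999, 1]),
            distortion=0.0,
        )
        assert flag_sparse(model, 1).tolist() == [9999]

    def test_balanced_clusters_not_flagged(self):
        model = ClusterModel(
            k=2,
            centroids=np.array([0.0, 1.0]),
            assignments=np.array([0] * 4998 + [1] * 5002),
            populations=np.array([4998, 5002]),
            distortion=0.0,
        )
        assert flag_sparse(model, 1).size == 0

    def test_threshold_n_flags_everything(self):
        model = kmeans_refine([0.0, 1.0, 10.0, 11.0], [0.5, 10.5])
        assert flag_sparse(model, 4).size == 4

    def test_threshold_zero_flags_nothing(self):
        model = kmeans_refine([0.0, 1.0], [0.5])
        assert flag_sparse(model, 0).size == 0

    @given(st.integers(2, 40), st.integers(1, 5), st.integers(0, 3))
    def test_flag_count_bounded_by_threshold_times_k(self, n, k, threshold):
        rng = np.random.default_rng(n * 100 + k)
        x = rng.normal(0, 1, n)
        k = min(k, np.unique(x).size)
        model = hkmeans(x, k)
        assert flag_sparse(model, threshold).size <= threshold * model.k
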