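import numpy as np
import pytest

from wingmorph.errors import InputValidationError, NumericalError
from wingmorph.shape_stats import (DistanceResult, fit_da,
                                   jackknife_shape_classification,
                                   mahalanobis_matrix, mean_shapes, pca,
                                   permutation_test_distances, upgma)
from wingmorph.size_stats import adjusted_accuracy

from _oracles import mahalanobis_oracle, upgma_heights_oracle


def make_clusters(rng, centers, n_per, sd=1.0):
    X = np.vstack([rng.normal(c, sd, size=(n, len(c)))
                   for c, n in zip(centers, n_per)])
    labels = np.concatenate([[f"g{i}"] * n for i, n in enumerate(n_per)])
    return X, labels


class TestPca:
    def test_collinear_data_needs_one_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(0, 1, 40)
        direction = np.array([1.0, -2.0, 0.5, 3.0, 1.0])
        X = np.outer(t, direction)
        p = pca(X, retention=0.99)
        assert p.variance_proportions[0] == pytest.approx(1.0, abs=1e-12)
        assert p.n_retained == 1

    def test_trace_conservation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (50, 8))
        p = pca(X)
        total_var = np.sum(np.var(X, axis=0, ddof=1))
        assert p.eigenvalues.sum() == pytest.approx(total_var, rel=1e-9)

    def test_scores_reconstruct_centered_data(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (30, 6))
        p = pca(X)
        np.testing.assert_allclose(p.scores @ p.loadings.T, X - p.mean,
                                   atol=1e-9)

    def test_constant_matrix_rejected(self):
        with pytest.raises(NumericalError, match="variance"):
            pca(np.ones((10, 4)))


class TestDiscriminantAnalysis:
    def test_two_groups_one_axis(self):
        rng = np.random.default_rng(3)
        X, labels = make_clusters(rng, [[0.0], [5.0]], [10, 10])
        p = pca(X, retention=1.0)
        m = fit_da(p, labels)
        assert m.axes.shape[1] == 1
        assert m.proportions[0] == pytest.approx(1.0)

    def test_four_groups_three_axes(self):
        rng = np.random.default_rng(4)
        centers = [[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4]]
        X, labels = make_clusters(rng, centers, [12, 12, 12, 12])
        m = fit_da(pca(X, retention=1.0), labels)
        assert m.axes.shape[1] == 3
        assert m.proportions.sum() == pytest.approx(1.0)
        assert np.all(np.diff(m.axis_eigenvalues) <= 1e-12)

    def test_canonical_scores_whitened(self):
        rng = np.random.default_rng(5)
        centers = [[0, 0, 0, 0], [3, 1, 0, 0], [0, 3, 1, 0]]
        X, labels = make_clusters(rng, centers, [15, 15, 15])
        m = fit_da(pca(X, retention=1.0), labels)
        # pooled within-group variance of canonical scores = 1 per axis
        uniq = sorted(set(labels))
        scatter = np.zeros(m.scores.shape[1])
        for g in uniq:
            S = m.scores[labels == g]
            scatter += np.sum((S - S.mean(axis=0)) ** 2, axis=0)
        pooled = scatter / (len(labels) - len(uniq))
        np.testing.assert_allclose(pooled, 1.0, atol=1e-9)


class TestMahalanobis:
    def test_identical_means_zero(self):
        rng = np.random.default_rng(6)
        noise = rng.normal(0, 1, (20, 3))
        X = np.vstack([noise, noise])
        labels = np.array(["a"] * 20 + ["b"] * 20)
        m = fit_da(pca(X, retention=1.0), labels)
        D = mahalanobis_matrix(m).distances
        assert D[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_identity_covariance_closed_form(self):
        # construct two groups whose pooled within-group covariance is
        # exactly the identity and whose means are (0,0) and (3,0):
        # the Mahalanobis distance is then exactly 3
        rng = np.random.default_rng(7)

        def whitened(n):
            Z = rng.normal(0, 1, (n, 2))
            Z = Z - Z.mean(axis=0)
            C = Z.T @ Z / (n - 1)
            return Z @ np.linalg.inv(np.linalg.cholesky(C)).T

        X = np.vstack([whitened(20), whitened(20) + [3.0, 0.0]])
        labels = np.array(["a"] * 20 + ["b"] * 20)
        m = fit_da(pca(X, retention=1.0), labels)
        D = mahalanobis_matrix(m).distances
        assert D[0, 1] == pytest.approx(3.0, rel=1e-9)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        centers = [[0, 0, 0, 0], [2, 0, 1, 0], [0, 2, 0, 1], [1, 1, 1, 1]]
        X, labels = make_clusters(rng, centers, [15, 12, 18, 10])
        m = fit_da(pca(X, retention=1.0), labels)
        D = mahalanobis_matrix(m).distances
        D_ref = mahalanobis_oracle(pca(X, retention=1.0).retained_scores,
                                   labels)
        np.testing.assert_allclose(D, D_ref, atol=1e-9)

    def test_invariance_under_linear_transform(self):
        rng = np.random.default_rng(9)
        centers = [[0, 0, 0], [3, 1, 0], [0, 2, 2]]
        X, labels = make_clusters(rng, centers, [15, 15, 15])
        A = rng.normal(0, 1, (3, 3)) + 3 * np.eye(3)
        D1 = mahalanobis_oracle(X, labels)
        D2 = mahalanobis_oracle(X @ A.T, labels)
        np.testing.assert_allclose(D1, D2, atol=1e-8)


class TestPermutationDistances:
    def test_p_values_in_range_and_granular(self):
        rng = np.random.default_rng(10)
        X, labels = make_clusters(rng, [[0, 0], [0.2, 0], [5, 5]],
                                  [10, 10, 10])
        res = permutation_test_distances(X, labels, R=99, seed=11,
                                         retention=1.0)
        off = ~np.eye(3, dtype=bool)
        p = res.p_values[off]
        assert np.all((p > 0) & (p <= 1))
        # granularity: multiples of 1/(R+1)
        np.testing.assert_allclose(p * 100, np.round(p * 100), atol=1e-9)

    def test_separated_pair_flagged(self):
        rng = np.random.default_rng(12)
        X, labels = make_clusters(rng, [[0, 0], [10, 0]], [15, 15])
        res = permutation_test_distances(X, labels, R=199, seed=13,
                                         retention=1.0)
        assert res.p_values[0, 1] == pytest.approx(1 / 200)
        assert res.significant[0, 1]

    def test_zero_distance_p_one(self):
        rng = np.random.default_rng(14)
        noise = rng.normal(0, 1, (12, 2))
        X = np.vstack([noise, noise])
        labels = np.array(["a"] * 12 + ["b"] * 12)
        res = permutation_test_distances(X, labels, R=49, seed=15,
                                         retention=1.0)
        assert res.p_values[0, 1] == 1.0


class TestJackknifeShape:
    def test_separable_clusters_kappa_one(self):
        rng = np.random.default_rng(16)
        centers = [[0, 0, 0], [20, 0, 0], [0, 20, 0], [0, 0, 20]]
        X, labels = make_clusters(rng, centers, [10, 10, 10, 10])
        rep = jackknife_shape_classification(X, labels, retention=1.0)
        kappa, _ = adjusted_accuracy(rep)
        assert kappa == pytest.approx(1.0)

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(17)
        kappas = []
        for _ in range(3):
            X = rng.normal(0, 1, (60, 4))
            labels = rng.permutation(np.repeat(["a", "b", "c"], 20))
            rep = jackknife_shape_classification(X, labels, retention=1.0)
            kappas.append(adjusted_accuracy(rep)[0])
        assert abs(np.mean(kappas)) < 0.15

    def test_published_counts_through_report(self):
        # printed wing-contour shape block: per-group correct
        # (15, 29, 22, 14) of (30, 41, 35, 22) -> Po = 80/128, adjusted 49%
        from wingmorph.size_stats import ClassificationReport
        rep = ClassificationReport.from_counts(
            ["c", "f", "h", "v"], [30, 41, 35, 22], [15, 29, 22, 14])
        assert rep.observed_accuracy == pytest.approx(80 / 128)
        assert adjusted_accuracy(rep)[1] == 49


class TestMeanShapes:
    def test_identical_shapes_mean_equals_each(self):
        X = np.tile([1.0, 2.0, 3.0], (5, 1))
        m = mean_shapes(X, ["g"] * 5)
        np.testing.assert_allclose(m["g"], [1, 2, 3])

    def test_opposite_vectors_cancel(self):
        v = np.array([1.0, -2.0, 0.5])
        m = mean_shapes(np.vstack([v, -v]), ["g", "g"])
        np.testing.assert_allclose(m["g"], 0.0, atol=1e-15)

    def test_mean_minimizes_summed_squared_distance(self):
        rng = np.random.default_rng(18)
        X = rng.normal(0, 1, (20, 6))
        m = mean_shapes(X, ["g"] * 20)["g"]
        obj = np.sum((X - m) ** 2)
        for _ in range(20):
            cand = m + rng.normal(0, 0.1, 6)
            assert np.sum((X - cand) ** 2) >= obj


class TestUpgma:
    def dist(self, groups, D):
        return DistanceResult(groups=tuple(groups),
                              distances=np.asarray(D, dtype=float))

    def test_hand_computed_three_leaves(self):
        tree = upgma(self.dist("ABC", [[0, 2, 8], [2, 0, 8], [8, 8, 0]]))
        assert tree.newick == "((A:1,B:1):3,C:4);"
        assert tree.merge_heights == (1.0, 4.0)
        assert tree.clusters[0] == frozenset("AB")

    def test_ultrametric_input_reproduced(self):
        # heights: (a,b) at 1, ((a,b),c) at 2.5
        D = [[0, 2, 5], [2, 0, 5], [5, 5, 0]]
        tree = upgma(self.dist(["a", "b", "c"], D))
        assert tree.merge_heights == (1.0, 2.5)

    def test_merge_heights_non_decreasing_random(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            n = rng.integers(3, 9)
            M = rng.uniform(1, 10, (n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0.0)
            tree = upgma(self.dist([f"L{i}" for i in range(n)], D))
            assert all(h2 >= h1 - 1e-12 for h1, h2 in
                       zip(tree.merge_heights, tree.merge_heights[1:]))

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(20)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            M = rng.uniform(1, 10, (n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0.0)
            tree = upgma(self.dist([f"L{i}" for i in range(n)], D))
            np.testing.assert_allclose(np.sort(tree.merge_heights),
                                       upgma_heights_oracle(D), atol=1e-9)

    def test_ultrametric_root_to_leaf_equal(self):
        rng = np.random.default_rng(21)
        M = rng.uniform(1, 10, (6, 6))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        tree = upgma(self.dist([f"L{i}" for i in range(6)], D))
        # parse branch lengths back: root height equals max merge height
        assert tree.merge_heights[-1] == max(tree.merge_heights)

    def test_asymmetric_rejected(self):
        with pytest.raises(InputValidationError):
            upgma(self.dist("AB", [[0, 1], [2, 0]]))
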