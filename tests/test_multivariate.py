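import numpy as np
import pytest
from scipy import stats

from phylomorph.multivariate import (CvaResult, EllipseSpec, cva,
                                     ellipse_contains, equal_frequency_ellipse,
                                     group_total_variance, pca,
                                     permutation_test)


class TestPca:
    def test_collinear_scatter_gives_pc1_everything(self, rng):
        t = rng.normal(size=50)
        direction = np.array([1.0, 2.0, -1.0, 0.5])
        x = np.outer(t, direction) + 3.0
        res = pca(x)
        assert res.variance_proportions[0] == pytest.approx(1.0, abs=1e-12)

    def test_proportions_sum_to_one(self, small_study):
        sample, _, _ = small_study
        res = pca(sample)
        assert res.variance_proportions.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(res.eigenvalues) <= 1e-15)

    def test_axes_orthonormal(self, small_study):
        res = pca(small_study[0])
        gram = res.axes @ res.axes.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-10)

    def test_matches_dense_covariance_eigendecomposition(self, rng):
        x = rng.normal(size=(40, 6))
        res = pca(x)
        cov = np.cov(x, rowvar=False, ddof=1)
        expected = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(res.eigenvalues, expected[:len(res.eigenvalues)],
                                   atol=1e-9)

    def test_reconstruction(self, small_study):
        sample, _, _ = small_study
        res = pca(sample)
        rebuilt = res.scores @ res.axes + res.mean
        np.testing.assert_allclose(rebuilt, sample.tangent_coords, atol=1e-8)

    def test_too_few_specimens(self, rng):
        with pytest.raises(ValueError):
            pca(rng.normal(size=(2, 4)))


class TestGroupTotalVariance:
    def test_identical_members_zero(self):
        x = np.tile([1.0, 2.0, 3.0], (5, 1))
        assert group_total_variance(x, [0, 1, 2, 3]) == pytest.approx(0.0)

    def test_equals_sum_of_subset_eigenvalues(self, small_study):
        sample, _, labels = small_study
        members = [i for i, l in enumerate(labels) if l == labels[0]]
        tv = group_total_variance(sample, members)
        sub_eig = pca(sample.tangent_coords[members]).eigenvalues
        assert tv == pytest.approx(sub_eig.sum(), abs=1e-12)

    def test_isotropic_noise_expectation(self, rng):
        # total variance of isotropic noise ~ d * sigma^2
        sigma, d, n = 0.3, 8, 2000
        x = rng.normal(0, sigma, size=(n, d))
        assert group_total_variance(x, np.arange(n)) == pytest.approx(
            d * sigma ** 2, rel=0.05)

    def test_single_member_rejected(self, rng):
        with pytest.raises(ValueError):
            group_total_variance(rng.normal(size=(5, 3)), [2])


class TestEqualFrequencyEllipse:
    def test_isotropic_normal_closed_form(self, rng):
        pts = rng.normal(size=(5000, 2))
        spec = equal_frequency_ellipse(pts, coverage=0.90)
        expected = np.sqrt(stats.chi2.ppf(0.90, 2))
        np.testing.assert_allclose(spec.semi_axes, expected, rtol=0.05)

    def test_empirical_coverage(self, rng):
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        pts = rng.multivariate_normal([3, -1], cov, size=5000)
        spec = equal_frequency_ellipse(pts, coverage=0.90)
        frac = ellipse_contains(spec, pts).mean()
        assert 0.88 <= frac <= 0.92

    def test_scale_equivariance(self, rng):
        pts = rng.multivariate_normal([0, 0], [[3, 1], [1, 1]], size=400)
        a = equal_frequency_ellipse(pts)
        b = equal_frequency_ellipse(pts * 3.0)
        np.testing.assert_allclose(b.semi_axes, 3.0 * a.semi_axes, rtol=1e-10)
        assert b.angle == pytest.approx(a.angle, abs=1e-10)

    def test_singular_scatter_rejected(self):
        line = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="degenerate|singular"):
            equal_frequency_ellipse(line)


class TestCva:
    def test_identity_covariance_mahalanobis_is_euclidean(self, rng):
        # two groups with (population) identity within-group covariance
        n = 2000
        delta = np.array([1.3, 0.0, 0.0, 0.0])
        x = np.vstack([rng.normal(size=(n, 4)), rng.normal(size=(n, 4)) + delta])
        labels = ["a"] * n + ["b"] * n
        res = cva(x, labels, retained_dims=4)
        assert res.mahalanobis[0, 1] == pytest.approx(np.linalg.norm(delta),
                                                      rel=0.05)

    def test_number_of_canonical_axes(self, small_study):
        sample, _, labels = small_study
        res = cva(sample, labels)
        assert res.canonical_axes.shape[0] == min(3 - 1, res.retained_dims)

    def test_matches_brute_force_pooled_inverse(self, rng):
        x = rng.normal(size=(30, 4))
        x[10:20] += [2, 0, 0, 0]
        x[20:] += [0, 3, 1, 0]
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        res = cva(x, labels, retained_dims=4)
        # brute force in the original 4D space
        mus = [x[i * 10:(i + 1) * 10].mean(axis=0) for i in range(3)]
        scatter = sum(np.cov(x[i * 10:(i + 1) * 10], rowvar=False, ddof=1) * 9
                      for i in range(3))
        s_inv = np.linalg.inv(scatter / (30 - 3))
        for i in range(3):
            for j in range(3):
                diff = mus[i] - mus[j]
                expected = np.sqrt(diff @ s_inv @ diff)
                assert res.mahalanobis[i, j] == pytest.approx(expected, abs=1e-8)

    def test_invariant_under_linear_transform(self, rng):
        x = rng.normal(size=(45, 5))
        x[15:30] += 1.0
        x[30:] -= 1.0
        labels = ["a"] * 15 + ["b"] * 15 + ["c"] * 15
        base = cva(x, labels, retained_dims=5).mahalanobis
        for _ in range(3):
            a = rng.normal(size=(5, 5)) + 2 * np.eye(5)
            res = cva(x @ a, labels, retained_dims=5).mahalanobis
            np.testing.assert_allclose(res, base, atol=1e-6 * base.max())

    def test_small_group_rejected(self, rng):
        x = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="fewer than 2"):
            cva(x, ["a", "a", "a", "a", "b"])

    def test_retained_dims_exceeding_rank_rejected(self, rng):
        x = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            cva(x, ["a"] * 5 + ["b"] * 5, retained_dims=7)

    def test_group_shape_distances_on_study(self, small_study):
        sample, _, labels = small_study
        res = cva(sample, labels)
        assert res.procrustes_d is not None
        assert np.all(res.procrustes_d[np.triu_indices(3, 1)] > 0.05)
        np.testing.assert_allclose(res.procrustes_d, res.procrustes_d.T)
        np.testing.assert_allclose(np.diag(res.procrustes_d), 0.0)

    def test_mahalanobis_ordering_tracks_true_separation(self, rng):
        # equal spherical covariances: Mahalanobis order = mean-separation order
        mus = {"a": np.zeros(6), "b": np.r_[2.0, np.zeros(5)],
               "c": np.r_[5.0, np.zeros(5)]}
        x = np.vstack([rng.normal(size=(100, 6)) + mus[g] for g in "abc"])
        labels = sum([[g] * 100 for g in "abc"], [])
        m = cva(x, labels, retained_dims=6).mahalanobis
        # true separations: ab=2 < ac=5, bc=3 < ac=5, ab=2 < bc=3
        assert m[0, 1] < m[1, 2] < m[0, 2]


class TestPermutationTest:
    def test_boundary_single_permutation(self, rng):
        x = rng.normal(size=(12, 3))
        res = permutation_test(x, ["a"] * 6 + ["b"] * 6, "mahalanobis",
                               n_perm=1, seed=0)
        assert res.p_values[0, 1] in (0.5, 1.0)

    def test_minimal_p_for_separated_groups(self, rng):
        x = np.vstack([rng.normal(size=(20, 4)),
                       rng.normal(size=(20, 4)) + 10.0])
        labels = ["a"] * 20 + ["b"] * 20
        res = permutation_test(x, labels, "mahalanobis", n_perm=999, seed=1)
        assert res.p_values[0, 1] == pytest.approx(1 / 1000)

    def test_p_never_zero_and_reproducible(self, small_study):
        sample, _, labels = small_study
        r1 = permutation_test(sample, labels, "procrustes", n_perm=99, seed=5)
        r2 = permutation_test(sample, labels, "procrustes", n_perm=99, seed=5)
        assert np.all(r1.p_values >= 1 / 100)
        np.testing.assert_array_equal(r1.p_values, r2.p_values)

    def test_study_groups_strongly_separated(self, small_study):
        sample, _, labels = small_study
        res = permutation_test(sample, labels, "procrustes", n_perm=199, seed=0)
        off = res.p_values[np.triu_indices(3, 1)]
        # a random permutation can recreate the observed split and tie, so the
        # guarantee is "at most one tie above the minimal attainable p"
        assert np.all(off <= 2 / 200)

    def test_null_p_roughly_uniform(self, rng):
        # small smoke version; the full calibration lives in the acceptance suite
        hits = 0
        n_sim = 60
        for s in range(n_sim):
            r = np.random.default_rng(1000 + s)
            x = r.normal(size=(24, 4))
            res = permutation_test(x, ["a"] * 12 + ["b"] * 12, "mahalanobis",
                                   n_perm=99, seed=s)
            if res.p_values[0, 1] <= 0.05:
                hits += 1
        assert hits <= 9  # ~ binomial(60, 0.05) upper tail

    def test_invalid_statistic(self, rng):
        with pytest.raises(ValueError):
            permutation_test(rng.normal(size=(8, 2)), ["a"] * 4 + ["b"] * 4,
                             "euclidean")
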