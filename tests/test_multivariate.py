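"""Scaling, PCA, Ward clustering, k-means and OPLS-DA/VIP."""

import numpy as np
import pytest
from scipy.cluster import hierarchy

import aromascreen as a
from aromascreen.multivariate import zscore, pca, hca_ward, kmeans, opls_da, vip, permutation_test
from conftest import two_cloud_data


class TestZScore:
    def test_simple_column(self):
        s = zscore(np.array([[1.0], [2.0], [3.0]]))
        assert s.values[:, 0] == pytest.approx([-1.0, 0.0, 1.0])
        assert s.mean[0] == 2.0 and s.sd[0] == 1.0

    def test_constant_column_flagged_and_zeroed(self):
        s = zscore(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 4.0]]))
        assert s.degenerate.tolist() == [True, False]
        assert np.all(s.values[:, 0] == 0.0)

    def test_scaled_columns_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        s = zscore(rng.normal(3.0, 7.0, size=(20, 6)))
        assert np.all(np.abs(s.values.mean(axis=0)) < 1e-12)
        assert s.values.std(axis=0, ddof=1) == pytest.approx(np.ones(6))


class TestPCA:
    def test_rank_one_matrix_concentrates_variance(self):
        u = np.array([1.0, -2.0, 0.5, 3.0])
        v = np.array([2.0, 1.0, -1.0])
        X = np.outer(u - u.mean(), v)
        s = a.ScaledMatrix(values=X, mean=np.zeros(3), sd=np.ones(3),
                           degenerate=np.zeros(3, bool))
        res = pca(s, 1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_ratios_sum_to_one_over_all_components(self):
        rng = np.random.default_rng(1)
        s = zscore(rng.normal(size=(8, 4)))
        res = pca(s, 4)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)
        assert np.all(res.explained_variance_ratio >= 0)

    def test_agrees_with_covariance_eigendecomposition(self):
        rng = np.random.default_rng(2)
        s = zscore(rng.normal(size=(6, 4)))
        res = pca(s, 3)
        cov = s.values.T @ s.values / (s.n_samples - 1)
        evals, evecs = np.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        ratio = evals / evals.sum()
        assert res.explained_variance_ratio == pytest.approx(ratio[:3], abs=1e-8)
        for j in range(3):
            dot = abs(evecs[:, j] @ res.loadings[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)
        # scores are the projections, uncorrelated columns
        proj = s.values @ res.loadings
        assert np.allclose(np.abs(proj), np.abs(res.scores), atol=1e-8)
        gram = res.scores.T @ res.scores
        assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(3)
        s = zscore(rng.normal(size=(10, 5)))
        res = pca(s, 3)
        for j in range(3):
            k = np.argmax(np.abs(res.loadings[:, j]))
            assert res.loadings[k, j] > 0

    def test_too_many_components_is_hard_error(self):
        s = zscore(np.random.default_rng(4).normal(size=(4, 6)))
        with pytest.raises(ValueError):
            pca(s, 4)  # limit is samples-1 = 3


def ward_bruteforce(points):
    """Greedy Ward merges computed directly from cluster centroids."""
    clusters = {i: [i] for i in range(len(points))}
    merges = []
    next_label = len(points)
    members = {i: frozenset([i]) for i in range(len(points))}
    while len(clusters) > 1:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if j <= i:
                    continue
                ci = points[clusters[i]].mean(axis=0)
                cj = points[clusters[j]].mean(axis=0)
                ni, nj = len(clusters[i]), len(clusters[j])
                d = np.sqrt(2.0 * ni * nj / (ni + nj)) * np.linalg.norm(ci - cj)
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((members[i], members[j], d))
        clusters[next_label] = clusters.pop(i) + clusters.pop(j)
        members[next_label] = members.pop(i) | members.pop(j)
        next_label += 1
    return merges


def merges_as_sets(result):
    """Convert an HCAResult to (member set a, member set b, height) rows."""
    n = result.n_items
    members = {i: frozenset([i]) for i in range(n)}
    rows = []
    for step, (la, lb, h, _) in enumerate(result.merges):
        sa, sb = members[int(la)], members[int(lb)]
        rows.append((sa, sb, h))
        members[n + step] = sa | sb
    return rows


class TestWard:
    def test_two_identical_items_merge_at_zero(self):
        res = hca_ward(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert res.merges.shape == (1, 4)
        assert res.merges[0, 2] == 0.0

    def test_outlier_merged_last(self):
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0]])
        res = hca_ward(pts)
        first = merges_as_sets(res)[0]
        assert {first[0], first[1]} == {frozenset([0]), frozenset([1])}
        assert res.merges[0, 2] == pytest.approx(1.0)  # Euclidean distance of the pair

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_on_5_points(self, seed):
        pts = np.random.default_rng(seed).normal(size=(5, 3))
        got = merges_as_sets(hca_ward(pts))
        expected = ward_bruteforce(pts)
        for (ga, gb, gh), (ea, eb, eh) in zip(got, expected):
            assert {ga, gb} == {ea, eb}
            assert gh == pytest.approx(eh, abs=1e-10)

    def test_matches_scipy_linkage(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(15, 4))
        got = hca_ward(pts).merges
        expected = hierarchy.linkage(pts, method="ward")
        assert np.allclose(np.sort(got[:, 2]), expected[:, 2], atol=1e-8)
        assert np.allclose(got[:, 3], expected[:, 3])

    def test_heights_nondecreasing_and_counts(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(20, 3))
        res = hca_ward(pts)
        assert res.merges.shape == (19, 4)
        assert np.all(np.diff(res.merges[:, 2]) >= -1e-12)
        assert res.merges[-1, 3] == 20


class TestKMeans:
    def test_k_equals_n_gives_zero_wcss(self):
        pts = np.random.default_rng(0).normal(size=(6, 2))
        res = kmeans(pts, k=6, seed=0, n_restarts=5)
        assert res.wcss == pytest.approx(0.0, abs=1e-20)

    def test_recovers_two_separated_clouds(self):
        X, truth = two_cloud_data(np.random.default_rng(1))
        res = kmeans(X, k=2, seed=0, n_restarts=10)
        # same partition up to label swap
        agreement = (res.labels == truth).mean()
        assert agreement in (0.0, 1.0)

    def test_duplicates_always_co_clustered(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(8, 3))
        X = np.vstack([base, base[:2]])  # rows 8,9 duplicate rows 0,1
        res = kmeans(X, k=3, seed=0)
        assert res.labels[8] == res.labels[0]
        assert res.labels[9] == res.labels[1]

    def test_wcss_trace_nonincreasing(self):
        X, _ = two_cloud_data(np.random.default_rng(3), n_per=15, sep=5.0)
        res = kmeans(X, k=4, seed=1, n_restarts=3)
        assert np.all(np.diff(res.wcss_trace) <= 1e-9)
        assert res.wcss == pytest.approx(res.wcss_trace[-1])

    def test_k_larger_than_n_is_hard_error(self):
        with pytest.raises(ValueError):
            kmeans(np.zeros((3, 2)), k=4, seed=0)


class TestOPLS:
    @staticmethod
    def planted(seed, n=6, p=10, effect=4.0):
        rng = np.random.default_rng(seed)
        y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
        X = rng.normal(size=(n, p))
        X[:, 0] += effect * y  # class-difference direction
        X[:, 1] += 3.0 * rng.normal(size=n)  # y-orthogonal nuisance
        return X, y

    def test_zero_ortho_equals_pls1_reference(self):
        from sklearn.cross_decomposition import PLSRegression

        X, y = self.planted(0)
        s = zscore(X)
        model = opls_da(s, y, n_ortho=0)
        yc = np.where(y == 1, 1.0, -1.0)
        sk = PLSRegression(n_components=1, scale=False).fit(s.values, yc - yc.mean())
        t_sk = sk.x_scores_[:, 0]
        sign = np.sign(t_sk @ model.t)
        assert np.allclose(model.t, sign * t_sk, atol=1e-10)

    def test_predictive_score_orthogonal_to_orthogonal_scores(self):
        X, y = self.planted(1)
        model = opls_da(zscore(X), y, n_ortho=2)
        for k in range(model.n_ortho):
            assert abs(model.t @ model.t_ortho[:, k]) < 1e-8

    def test_class_means_of_predictive_score_have_opposite_signs(self):
        X, y = self.planted(2)
        model = opls_da(zscore(X), y, n_ortho=1)
        by_class = model.predictive_scores_by_class()
        m0, m1 = (by_class[c].mean() for c in sorted(by_class))
        assert m0 * m1 < 0

    def test_r2y_stable_under_pure_noise_variable(self):
        X, y = self.planted(3)
        base = opls_da(zscore(X), y, n_ortho=1).r2y
        rng = np.random.default_rng(33)
        X2 = np.column_stack([X, rng.normal(size=X.shape[0])])
        aug = opls_da(zscore(X2), y, n_ortho=1).r2y
        assert abs(aug - base) < 0.05

    def test_r2y_in_unit_interval(self):
        X, y = self.planted(4)
        model = opls_da(zscore(X), y, n_ortho=1)
        assert 0.0 <= model.r2y <= 1.0
        assert 0.0 <= model.r2x <= 1.0

    def test_single_class_is_hard_error(self):
        X, _ = self.planted(5)
        with pytest.raises(ValueError, match="2 classes"):
            opls_da(zscore(X), np.zeros(X.shape[0], int), n_ortho=1)


class TestVIP:
    def test_identical_variables_all_vip_one(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=8)
        X = np.tile(col[:, None], (1, 5))
        y = (col > np.median(col)).astype(int)
        model = opls_da(zscore(X), y, n_ortho=0)
        assert model.vip == pytest.approx(np.ones(5))

    def test_normalization_identity(self):
        X, y = TestOPLS.planted(6, p=13)
        model = opls_da(zscore(X), y, n_ortho=1)
        assert abs((model.vip**2).sum() - 13) < 1e-8
        inclusive = vip(model, include_orthogonal=True)
        assert abs((inclusive**2).sum() - 13) < 1e-8

    def test_informative_variable_wins_argmax(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n, p = 6, 12
            y = np.r_[np.zeros(3, int), np.ones(3, int)]
            X = rng.normal(size=(n, p))
            X[:, 4] += 5.0 * y
            model = opls_da(zscore(X), y, n_ortho=0)
            hits += int(np.argmax(model.vip) == 4)
        assert hits >= 95


class TestPermutationTest:
    def test_p_is_bounded(self):
        X, y = TestOPLS.planted(0)
        p = permutation_test(zscore(X), y, n_ortho=0, n_perm=19, seed=0)
        assert 0 < p <= 1

    def test_planted_effect_detected(self):
        # consistent class shift across several variables, as the
        # generator produces at 5% replicate CV: 3 vs 3, n_perm=99
        low = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = np.r_[np.zeros(3, int), np.ones(3, int)]
            X = rng.normal(size=(6, 8))
            X[:, :5] += 8.0 * y[:, None]
            p = permutation_test(zscore(X), y, n_ortho=0, n_perm=99, seed=seed)
            low += int(p <= 0.05)
        assert low >= 90

    def test_null_calibration(self):
        ps = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(8, 6))
            y = np.r_[np.zeros(4, int), np.ones(4, int)]
            ps.append(permutation_test(zscore(X), y, n_ortho=0, n_perm=199, seed=seed))
        assert 0.3 <= np.mean(ps) <= 0.7
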