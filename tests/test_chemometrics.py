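"""Z-scoring, clustering, PCA, OPLS-DA/VIP, permutation test, t-test."""

import math

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.integrate import quad

from flavoromics.chemometrics import (
    compute_vip,
    fit_oplsda,
    fit_pca,
    hcluster_order,
    permutation_test,
    ttest_independent,
    zscore,
    zscore_rows,
)

from conftest import make_peak_table


# ---------------------------------------------------------------------------
# Z-score
# ---------------------------------------------------------------------------

class TestZscore:
    def test_simple_row(self):
        assert np.allclose(zscore_rows(np.array([[1.0, 2.0, 3.0]])), [[-1, 0, 1]])

    def test_constant_row_maps_to_zeros(self):
        assert np.array_equal(zscore_rows(np.array([[5.0, 5.0, 5.0]])), [[0, 0, 0]])

    def test_rows_standardized(self):
        rng = np.random.default_rng(2)
        z = zscore_rows(rng.normal(3, 2, size=(20, 8)))
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_idempotent_on_nonconstant_rows(self):
        rng = np.random.default_rng(3)
        z = zscore_rows(rng.normal(size=(5, 6)))
        assert np.allclose(zscore_rows(z), z, atol=1e-9)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            zscore_rows(np.array([[1.0]]))

    def test_peak_table_wrapper_carries_labels(self, small_table):
        z = zscore(small_table)
        assert z.compound_ids == small_table.compound_ids()
        assert z.samples == small_table.samples


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

def naive_average_linkage_merges(x):
    """O(n³) agglomeration oracle; returns the merge sequence as frozensets."""
    clusters = [frozenset([i]) for i in range(len(x))]
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = np.mean(
                    [d[i, j] for i in clusters[a] for j in clusters[b]]
                )
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append(frozenset({clusters[a], clusters[b]}))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return merges


def linkage_merge_sequence(x):
    link = sch.linkage(x, method="average", metric="euclidean")
    n = len(x)
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for k, (a, b, _, _) in enumerate(link):
        ca, cb = members[int(a)], members[int(b)]
        merges.append(frozenset({ca, cb}))
        members[n + k] = ca | cb
    return merges


class TestHclusterOrder:
    def test_identical_pair_adjacent(self):
        x = np.array([[0.0, 0.0], [10.0, 10.0], [0.0, 0.0]])
        order = list(hcluster_order(x))
        pos0, pos2 = order.index(0), order.index(2)
        assert abs(pos0 - pos2) == 1

    def test_merge_sequence_matches_naive_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.normal(size=(6, 3))
            assert linkage_merge_sequence(x) == naive_average_linkage_merges(x)

    def test_single_item_axis_identity(self):
        assert list(hcluster_order(np.ones((1, 4)))) == [0]

    def test_permutation_of_indices(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(9, 4))
        order = hcluster_order(x)
        assert sorted(order) == list(range(9))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPca:
    def test_collinear_data_pc1_explains_all(self):
        t = np.linspace(-2, 2, 6)
        x = np.outer(t, [1.0, 2.0])  # all samples on a line
        m = fit_pca(x.T, 1)
        assert m.explained_percent[0] == pytest.approx(100.0)

    def test_known_covariance_eigen_ratios(self):
        # centered samples with X'X = [[10, 8], [8, 10]] → eigenvalues 18, 2
        xc = np.array([[2.0, 1.0], [-2.0, -1.0], [1.0, 2.0], [-1.0, -2.0]])
        m = fit_pca(xc.T, 2)
        assert np.allclose(m.explained_percent, [90.0, 10.0], atol=1e-9)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(12, 5))  # vars × samples layout
        k = 4  # = n_samples − 1, full rank of the centered matrix
        m = fit_pca(x, k)
        recon = m.scores @ m.loadings.T
        centered = x.T - x.T.mean(axis=0, keepdims=True)
        assert np.allclose(recon, centered, atol=1e-9)

    def test_loadings_orthonormal_scores_orthogonal(self):
        rng = np.random.default_rng(5)
        m = fit_pca(rng.normal(size=(10, 7)), 3)
        assert np.allclose(m.loadings.T @ m.loadings, np.eye(3), atol=1e-9)
        g = m.scores.T @ m.scores
        assert np.allclose(g - np.diag(np.diag(g)), 0, atol=1e-8)

    def test_explained_invariant_to_sample_order(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(8, 5))
        perm = rng.permutation(5)
        a = fit_pca(x, 2).explained_percent
        b = fit_pca(x[:, perm], 2).explained_percent
        assert np.allclose(a, b, atol=1e-9)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.ones((5, 4)), 4)

    def test_agrees_with_sklearn(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(9)
        x = rng.normal(size=(15, 6))  # vars × samples
        m = fit_pca(x, 3)
        sk = sklearn.PCA(n_components=3).fit(x.T)
        assert np.allclose(
            m.explained_percent, 100 * sk.explained_variance_ratio_, atol=1e-8
        )


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

def _two_clusters(n_per=10, dist=10.0, p=8, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_per, p))
    b = rng.normal(0, 1, size=(n_per, p))
    b[:, 0] += dist
    X = np.vstack([a, b])
    y = ["A"] * n_per + ["B"] * n_per
    return X, y


def nipals_pls1(X, y01):
    """Textbook single-component PLS1 by NIPALS iteration (oracle)."""
    xc = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    xc = xc / sd
    yc = y01 - y01.mean()
    u = yc.copy()
    for _ in range(100):
        w = xc.T @ u / (u @ u)
        w = w / np.linalg.norm(w)
        t = xc @ w
        q = yc @ t / (t @ t)
        u_new = yc * q / (q * q)
        if np.allclose(u_new, u, atol=1e-12):
            break
        u = u_new
    return w, t, q


class TestOplsda:
    def test_separable_clusters_fit_well(self):
        X, y = _two_clusters(seed=1)
        m = fit_oplsda(X, y, seed=0)
        assert m.r2y > 0.95
        assert m.q2 > 0.9

    def test_zero_ortho_equals_nipals_pls1_oracle(self):
        X, y = _two_clusters(n_per=6, dist=3.0, seed=2)
        m = fit_oplsda(X, y, k_ortho=0, seed=0)
        y01 = np.array([0.0] * 6 + [1.0] * 6)
        w, t, q = nipals_pls1(X, y01)
        sign = np.sign(w @ m.w_pred)
        assert np.allclose(m.w_pred, sign * w, atol=1e-9)
        assert np.allclose(m.t_pred, sign * t, atol=1e-8)
        assert m.q_pred * sign == pytest.approx(q, abs=1e-9)

    def test_scores_unchanged_when_no_orthogonal_variation(self):
        # X is exactly rank-1 along the class direction: nothing orthogonal
        y01 = np.array([0.0] * 5 + [1.0] * 5)
        p_dir = np.array([1.0, -2.0, 0.5, 3.0])
        X = np.outer(y01 - y01.mean(), p_dir)
        y = ["A"] * 5 + ["B"] * 5
        m0 = fit_oplsda(X, y, k_ortho=0, seed=0, scale=False)
        m2 = fit_oplsda(X, y, k_ortho=2, seed=0, scale=False)
        assert m2.k_ortho == 0  # orthogonal extraction finds nothing
        s0, s2 = m0.t_pred, m2.t_pred
        sign = np.sign(s0 @ s2)
        assert np.allclose(s0, sign * s2, atol=1e-9)

    def test_r2_quantities_in_range(self):
        X, y = _two_clusters(n_per=5, dist=3.0, seed=3)
        m = fit_oplsda(X, y, seed=0)
        assert 0 <= m.r2x <= 1
        assert 0 <= m.r2y <= 1
        assert m.q2 <= 1

    def test_more_than_two_classes_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError, match="2 classes"):
            fit_oplsda(X, ["A", "A", "B", "B", "C", "C"])

    def test_tiny_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(4, 3))
        with pytest.raises(ValueError, match="2 samples"):
            fit_oplsda(X, ["A", "B", "B", "B"])

    def test_loo_used_when_few_samples(self):
        X, y = _two_clusters(n_per=3, dist=8.0, p=5, seed=4)
        m = fit_oplsda(X, y, seed=0)
        assert m.cv_folds == 6


class TestVip:
    def test_symmetric_variables_score_one(self):
        # two variables carrying identical information → both VIP = 1
        y01 = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        rng = np.random.default_rng(5)
        base = (y01 - 0.5) * 2 + rng.normal(0, 0.1, 6)
        X = np.column_stack([base, base])
        m = fit_oplsda(X, ["A"] * 3 + ["B"] * 3, k_ortho=0, seed=0)
        assert np.allclose(m.vip, [1.0, 1.0], atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mean_square_identity(self, seed):
        X, y = _two_clusters(n_per=4, dist=2.0, p=11, seed=seed)
        m = fit_oplsda(X, y, seed=seed)
        assert np.mean(m.vip ** 2) == pytest.approx(1.0, abs=1e-9)
        assert np.mean(compute_vip(m, "predictive") ** 2) == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_formula(self):
        X, y = _two_clusters(n_per=4, dist=2.0, p=6, seed=7)
        m = fit_oplsda(X, y, seed=0)
        weights = (
            np.column_stack([m.w_pred, m.w_ortho]) if m.k_ortho else m.w_pred[:, None]
        )
        ssy = m.ssy_per_component
        p = weights.shape[0]
        expected = np.sqrt(
            p
            * sum(
                ssy[a] * (weights[:, a] / np.linalg.norm(weights[:, a])) ** 2
                for a in range(weights.shape[1])
            )
            / ssy.sum()
        )
        assert np.allclose(m.vip, expected, atol=1e-12)


class TestPermutationTest:
    def test_reference_correlation_is_one(self):
        X, y = _two_clusters(n_per=4, dist=5.0, p=5, seed=8)
        res = permutation_test(X, y, n_perm=10, seed=0)
        assert res.reference[0] == 1.0
        assert res.triples.shape == (10, 3)

    def test_noise_q2_intercept_below_r2y_intercept(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 15))
        y = ["A"] * 5 + ["B"] * 5
        res = permutation_test(X, y, n_perm=20, seed=1)
        assert res.q2_intercept < res.r2y_intercept

    def test_separated_data_original_q2_beats_all_permuted(self):
        X, y = _two_clusters(n_per=5, dist=10.0, p=6, seed=10)
        res = permutation_test(X, y, n_perm=50, seed=2)
        assert res.reference[2] > res.triples[:, 2].max()

    def test_too_few_permutations_rejected(self):
        X, y = _two_clusters(n_per=3, p=4, seed=11)
        with pytest.raises(ValueError):
            permutation_test(X, y, n_perm=1)


# ---------------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------------

def t_cdf_numeric(t, df):
    """Student-t CDF by numerical integration of the density (oracle)."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    dens = lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2)  # noqa: E731
    val, _ = quad(dens, 0, abs(t))
    return 0.5 + math.copysign(val, t)


class TestTtest:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0]
        assert ttest_independent(a, a) == (0.0, 1.0)

    def test_pooled_matches_numeric_cdf_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        t, p = ttest_independent(a, b, "pooled")
        # hand-computed statistic: pooled variance, df = 4
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        t_hand = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(t_hand, abs=1e-12)
        p_oracle = 2 * (1 - t_cdf_numeric(abs(t_hand), 4))
        assert p == pytest.approx(p_oracle, abs=1e-9)

    def test_welch_matches_numeric_cdf_oracle(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [10.0, 20.0, 30.0]
        t, p = ttest_independent(a, b, "welch")
        va, vb = np.var(a, ddof=1) / 4, np.var(b, ddof=1) / 3
        t_hand = (np.mean(a) - np.mean(b)) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / 3 + vb ** 2 / 2)
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert p == pytest.approx(2 * (1 - t_cdf_numeric(abs(t_hand), df)), abs=1e-9)

    def test_swap_negates_t_preserves_p(self):
        a, b = [1.0, 3.0, 2.0], [5.0, 4.0, 7.0]
        t1, p1 = ttest_independent(a, b)
        t2, p2 = ttest_independent(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_unequal_means(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, p = ttest_independent([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0 and t == -np.inf

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            ttest_independent([1.0], [2.0, 3.0])
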