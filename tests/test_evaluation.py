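import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from coexgraph.evaluation import (
    ari,
    cofunction_auc,
    db_index,
    double_center_similarity,
    gaussian_raster_kernel,
    nmi,
    pearson_distance,
    rasterize,
    weighted_euclid_distance,
)


class TestDBIndex:
    def test_two_tight_clusters(self):
        # clusters {0,1} and {10,11}: d_i = 1, centroid distance 10 -> 0.2
        pts = np.array([0.0, 1.0, 10.0, 11.0])
        labels = np.array([0, 0, 1, 1])
        assert db_index(labels, pts) == pytest.approx(0.2)

    def test_separation_limit(self):
        pts = np.array([0.0, 1.0, 1000.0, 1001.0])
        labels = np.array([0, 0, 1, 1])
        assert db_index(labels, pts) < 0.01

    def test_matches_bruteforce_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n, k = 20, int(rng.integers(2, 5))
            pts = rng.normal(size=(n, 3))
            labels = rng.integers(k, size=n)
            labels[:k] = np.arange(k)  # every cluster nonempty
            got = db_index(labels, pts)
            # direct formula
            ids = np.unique(labels)
            d = {}
            cent = {}
            for c in ids:
                idx = np.flatnonzero(labels == c)
                cent[c] = pts[idx].mean(axis=0)
                if idx.size < 2:
                    d[c] = 0.0
                else:
                    s = 0.0
                    for p in idx:
                        for q in idx:
                            if p != q:
                                s += np.linalg.norm(pts[p] - pts[q])
                    d[c] = s / (idx.size * (idx.size - 1))
            total = 0.0
            for a in ids:
                total += max(
                    (d[a] + d[b]) / np.linalg.norm(cent[a] - cent[b])
                    for b in ids if b != a
                )
            assert got == pytest.approx(total / len(ids))

    def test_monotone_in_separation(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(30, 2))
        labels = np.repeat([0, 1, 2], 10)
        vals = []
        for scale in (1.0, 3.0, 10.0):
            pts = base + scale * np.array([[0, 0]] * 10 + [[5, 0]] * 10 + [[0, 5]] * 10)
            vals.append(db_index(labels, pts))
        assert vals == sorted(vals, reverse=True)

    def test_singleton_cluster_warns(self):
        with pytest.warns(UserWarning, match="singleton"):
            db_index(np.array([0, 1, 1]), np.array([0.0, 5.0, 6.0]))

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError):
            db_index(np.zeros(4), np.arange(4.0))


class TestDistances:
    def test_pearson_self_zero_anticorrelated_two(self):
        x = np.linspace(0, 1, 9)
        expr = np.column_stack([x, -x, x * 2])
        d = pearson_distance(expr)
        assert d[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 1] == pytest.approx(2.0)
        assert d[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_pearson_matches_numpy_oracle(self):
        rng = np.random.default_rng(2)
        expr = rng.normal(size=(12, 5))
        d = pearson_distance(expr)
        np.testing.assert_allclose(d, 1 - np.corrcoef(expr.T), atol=1e-10)

    def test_weighted_euclid_identical_rasters_zero(self):
        rng = np.random.default_rng(3)
        coords = np.array([[r, c] for r in range(5) for c in range(5)], float)
        g = rng.random(25)
        expr = np.column_stack([g, g])
        d = weighted_euclid_distance(expr, coords, (5, 5), bandwidth=1.0)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_identity_kernel_reduces_to_plain_euclid(self):
        rng = np.random.default_rng(4)
        coords = np.array([[r, c] for r in range(4) for c in range(4)], float)
        expr = rng.random((16, 3))
        d = weighted_euclid_distance(expr, coords, (4, 4), W=sp.eye(16))
        rasters = rasterize(expr, coords, (4, 4))
        expected = np.linalg.norm(rasters[0] - rasters[1])
        assert d[0, 1] == pytest.approx(expected)

    def test_gaussian_kernel_tolerates_translation(self):
        # two one-hot rasters one cell apart: closer under a smooth kernel
        # than under the identity metric
        coords = np.array([[r, c] for r in range(3) for c in range(3)], float)
        a = np.zeros(9)
        b = np.zeros(9)
        a[4] = 1.0  # center cell
        b[5] = 1.0  # one step away
        expr = np.column_stack([a, b])
        d_smooth = weighted_euclid_distance(expr, coords, (3, 3), bandwidth=1.5)
        d_plain = weighted_euclid_distance(expr, coords, (3, 3), W=sp.eye(9))
        assert d_smooth[0, 1] < d_plain[0, 1]

    def test_empty_raster_errors(self):
        with pytest.raises(ValueError):
            rasterize(np.zeros((0, 2)), np.zeros((0, 2)), (3, 3))

    def test_kernel_symmetric(self):
        W = gaussian_raster_kernel((4, 5), bandwidth=1.0).toarray()
        np.testing.assert_allclose(W, W.T)


class TestARINMI:
    def test_identical_labelings(self):
        L = np.array([0, 0, 1, 1, 2])
        assert ari(L, L) == pytest.approx(1.0)
        assert nmi(L, L) == pytest.approx(1.0)

    def test_hand_contingency_case(self):
        # direct evaluation via the contingency-table formula
        L = [0, 0, 1, 1]
        P = [0, 1, 1, 1]
        assert ari(L, P) == pytest.approx(adjusted_rand_score(L, P))

    def test_matches_reference_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            a = rng.integers(4, size=n)
            b = rng.integers(4, size=n)
            assert ari(a, b) == pytest.approx(adjusted_rand_score(a, b), abs=1e-10)
            assert nmi(a, b) == pytest.approx(
                normalized_mutual_info_score(a, b), abs=1e-10)

    def test_random_labelings_ari_near_zero(self):
        rng = np.random.default_rng(6)
        vals = []
        for _ in range(1000):
            a = rng.integers(3, size=60)
            b = rng.integers(3, size=60)
            vals.append(ari(a, b))
        assert abs(np.mean(vals)) <= 0.02

    def test_nmi_single_class_conventions(self):
        assert nmi([0, 0, 0], [0, 0, 0]) == 1.0
        assert nmi([0, 1, 2], [5, 5, 5]) == 0.0

    def test_bounded_and_permutation_invariant(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.integers(3, size=30)
            b = rng.integers(3, size=30)
            assert ari(a, b) <= 1.0
            assert 0.0 <= nmi(a, b) <= 1.0
            remap = {0: 7, 1: 3, 2: 9}
            assert ari(a, np.vectorize(remap.get)(b)) == pytest.approx(ari(a, b))


class TestCofunction:
    def test_constant_similarity_gives_half_auc(self):
        # S all-ones: every gene's prediction for term j equals the same
        # constant, so ranking is uninformative -> AUC 0.5 (midranks).
        # Feeds the voting step directly, bypassing the centering.
        d, q = 30, 3
        rng = np.random.default_rng(8)
        A = (rng.random((d, q)) < 0.4).astype(float)
        S = np.ones((d, d))
        from coexgraph import evaluation as ev

        fold_of = np.random.default_rng(0).permutation(np.arange(d) % 3)
        P = (S @ A) / S.sum(axis=1)[:, None]
        for j in range(q):
            test = fold_of == 0
            truth = A[test, j]
            if truth.min() != truth.max():
                assert ev._auc(P[test, j], truth) == pytest.approx(0.5)

    def test_block_structure_gives_high_auc(self):
        d = 30
        genes_in_term = np.arange(10)
        # similarity blocks aligned with the annotation
        dist = np.ones((d, d))
        dist[np.ix_(genes_in_term, genes_in_term)] = 0.0
        dist[10:, 10:] = 0.0
        np.fill_diagonal(dist, 0.0)
        A = np.zeros((d, 2))
        A[genes_in_term, 0] = 1
        A[10:, 1] = 1
        aucs = cofunction_auc(dist, dist, A, w=0.5, seed=0)
        assert np.nanmin(aucs) >= 0.95

    def test_shuffled_annotations_near_half(self):
        rng = np.random.default_rng(9)
        d = 40
        X = rng.normal(size=(60, d))
        dp = pearson_distance(X)
        vals = []
        for seed in range(20):
            A = (np.random.default_rng(seed).random((d, 4)) < 0.3).astype(float)
            aucs = cofunction_auc(dp, dp, A, seed=seed)
            vals.extend([a for a in aucs if not np.isnan(a)])
        assert abs(np.mean(vals) - 0.5) <= 0.05

    def test_binary_annotation_required(self):
        with pytest.raises(ValueError):
            cofunction_auc(np.zeros((3, 3)), np.zeros((3, 3)), np.full((3, 2), 0.5))

    def test_double_centering_matches_formula(self):
        rng = np.random.default_rng(10)
        D = rng.random((6, 6))
        D = (D + D.T) / 2
        J = np.eye(6) - np.ones((6, 6)) / 6
        np.testing.assert_allclose(double_center_similarity(D), -0.5 * J @ D @ J)
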