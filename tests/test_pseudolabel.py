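import numpy as np
import pytest
import scipy.sparse as sp

import coexgraph as cg
from coexgraph.evaluation import ari
from coexgraph.pseudolabel import (
    center_radius,
    domain_subgraphs,
    filter_peripheral,
    hc_spots,
    initial_domains,
    neighbor_label_entropy,
    pseudo_label_cells,
    select_hc,
    spatial_adjacency,
)


def adj_from_edges(n, edges):
    rows = [i for i, j in edges] + [j for i, j in edges]
    cols = [j for i, j in edges] + [i for i, j in edges]
    return sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))


PATH5 = adj_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)])


class TestEntropy:
    def test_unanimous_neighbors_zero_entropy(self):
        assert neighbor_label_entropy(["a"] * 6) == 0.0

    def test_even_binary_split_one_bit(self):
        assert neighbor_label_entropy(["a"] * 3 + ["b"] * 3) == pytest.approx(1.0)

    def test_four_two_split(self):
        # -(4/6 log2 4/6 + 2/6 log2 2/6)
        assert neighbor_label_entropy(["a"] * 4 + ["b"] * 2) == pytest.approx(0.9183, abs=1e-4)

    def test_isolated_spot_is_nan(self):
        assert np.isnan(neighbor_label_entropy([]))


class TestPeripheralFilter:
    def test_homogeneous_labeling_retains_all(self):
        adj = sp.csr_matrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]]))
        kept = filter_peripheral(np.array(["a", "a", "a"]), adj)
        np.testing.assert_array_equal(kept, [0, 1, 2])

    def test_lone_dissenter_excluded_by_majority_clause(self):
        # center of a star disagrees with its 6 unanimous neighbors: H=0 <= e
        # but the majority label differs from its own.
        edges = [(0, i) for i in range(1, 7)] + [(i, i + 1) for i in range(1, 6)]
        adj = adj_from_edges(7, edges)
        labels = np.array(["b", "a", "a", "a", "a", "a", "a"])
        kept = filter_peripheral(labels, adj)
        assert 0 not in kept

    def test_checkerboard_matches_bruteforce(self):
        rows = cols = 6
        adj_list = cg.hex_neighbors((rows, cols), "square")
        labels = np.array([(r + c) % 2 for r in range(rows) for c in range(cols)]).astype(str)
        n = rows * cols
        mat = sp.lil_matrix((n, n))
        for i, neigh in enumerate(adj_list):
            for j in neigh:
                mat[i, j] = 1
        mat = sp.csr_matrix(mat)
        kept = set(filter_peripheral(labels, mat).tolist())
        # brute-force evaluation of both clauses
        H = np.empty(n)
        for i in range(n):
            H[i] = neighbor_label_entropy(labels[adj_list[i]])
        e = np.median(H[H > 0]) if np.any(H > 0) else np.inf
        expected = set()
        for i in range(n):
            neigh = labels[adj_list[i]]
            if H[i] <= e and 2 * np.sum(neigh == labels[i]) > len(neigh):
                expected.add(i)
        assert kept == expected  # checkerboard: nobody's neighbors agree
        assert kept == set()


class TestSubgraphsAndCenters:
    def test_small_islands_dropped(self):
        # one domain split into components of sizes 4 and 2 on a path
        adj = adj_from_edges(7, [(0, 1), (1, 2), (2, 3), (5, 6)])
        labels = np.array(["a"] * 7)
        subs = domain_subgraphs(np.arange(7), labels, adj, min_size=3)
        assert len(subs) == 1
        np.testing.assert_array_equal(subs[0][1], [0, 1, 2, 3])

    def test_components_match_bruteforce_union_find(self):
        rng = np.random.default_rng(0)
        n = 40
        edges = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.05]
        adj = adj_from_edges(n, edges) if edges else sp.csr_matrix((n, n))
        labels = rng.choice(["a", "b"], size=n)
        subs = domain_subgraphs(np.arange(n), labels, adj, min_size=1)
        # union-find oracle per label
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in edges:
            if labels[i] == labels[j]:
                parent[find(i)] = find(j)
        expected = {}
        for v in range(n):
            expected.setdefault((labels[v], find(v)), set()).add(v)
        got = {frozenset(vs.tolist()) for _, vs in subs}
        assert got == {frozenset(vs) for vs in expected.values()}

    def test_path_graph_center(self):
        centers, radius, ecc = center_radius(PATH5)
        np.testing.assert_array_equal(centers, [2])
        assert radius == 2
        np.testing.assert_array_equal(ecc, [4, 3, 2, 3, 4])

    def test_complete_graph_center_everywhere(self):
        n = 5
        adj = sp.csr_matrix(np.ones((n, n)) - np.eye(n))
        centers, radius, _ = center_radius(adj)
        np.testing.assert_array_equal(centers, np.arange(n))
        assert radius == 1

    def test_singleton_component(self):
        centers, radius, _ = center_radius(sp.csr_matrix((1, 1)))
        np.testing.assert_array_equal(centers, [0])
        assert radius == 0

    def test_disconnected_errors(self):
        adj = adj_from_edges(4, [(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="disconnected"):
            center_radius(adj)

    def test_radius_bounds_all_eccentricities(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(3, 12))
            edges = [(i, i + 1) for i in range(n - 1)]
            edges += [(int(rng.integers(n)), int(rng.integers(n))) for _ in range(n)]
            edges = [(i, j) for i, j in edges if i != j]
            adj = adj_from_edges(n, edges)
            _, radius, ecc = center_radius(adj)
            assert np.all(radius <= ecc)


class TestHCSelection:
    def test_path5_hc_set(self):
        centers, radius, _ = center_radius(PATH5)
        hc = select_hc(PATH5, centers, radius, fraction=0.6)
        np.testing.assert_array_equal(hc, [1, 2, 3])  # distances {2,1,0,1,2} < 1.2

    def test_singleton_center_always_included(self):
        adj = sp.csr_matrix((1, 1))
        hc = select_hc(adj, np.array([0]), 0, fraction=0.6)
        np.testing.assert_array_equal(hc, [0])

    def test_infinite_fraction_selects_all(self):
        centers, radius, _ = center_radius(PATH5)
        hc = select_hc(PATH5, centers, radius, fraction=np.inf)
        np.testing.assert_array_equal(hc, np.arange(5))

    def test_fraction_monotonicity(self):
        centers, radius, _ = center_radius(PATH5)
        sizes = [len(select_hc(PATH5, centers, radius, f)) for f in (0.3, 0.6, 1.0, 2.0)]
        assert sizes == sorted(sizes)


class TestStageOne:
    def test_hc_spots_subset_with_matching_labels(self, small_paired):
        paired, truth = small_paired
        hc = hc_spots(paired.srt)
        assert hc.provenance == "user"  # generator attaches true domain labels
        adj = spatial_adjacency(paired.srt.coordinates)
        retained = set(filter_peripheral(np.asarray(paired.srt.labels), adj).tolist())
        assert set(hc.hc_indices.tolist()) <= retained
        for idx, lab in zip(hc.hc_indices, hc.labels):
            assert str(paired.srt.labels[idx]) == str(lab)

    def test_user_labels_passed_through(self, small_paired):
        paired, _ = small_paired
        labels = np.asarray(paired.srt.labels)
        out = initial_domains(paired.srt)
        np.testing.assert_array_equal(out, labels)

    def test_default_backend_recovers_domains(self, small_paired):
        # bypass the user labels and cluster from expression + space alone
        from coexgraph.pseudolabel import default_spatial_backend

        paired, truth = small_paired
        spots = np.array([int(o[4:]) for o in paired.srt.obs_ids])
        pred = default_spatial_backend(paired.srt, n_domains=4)
        assert ari(truth.domain_of_spot[spots], pred) >= 0.8

    def test_backend_wrong_length_errors(self, small_paired):
        paired, _ = small_paired
        with pytest.raises(ValueError, match="wrong-length"):
            initial_domains(paired.srt, backend=lambda ds, k: np.zeros(3))

    def test_cell_pseudolabels_passthrough_and_recovery(self, small_paired):
        paired, truth = small_paired
        out = pseudo_label_cells(paired.sc)
        assert out.provenance == "user"
        assert len(out.hc_indices) == paired.sc.n_obs
        # 3 well-separated expression profiles, labels hidden
        rng = np.random.default_rng(0)
        types = rng.integers(3, size=240)
        mu = np.zeros((240, 30))
        for t in range(3):
            mu[types == t, 10 * t:10 * (t + 1)] = 25.0
        counts = rng.poisson(mu + 1.0)
        ds = cg.ExpressionDataset(counts, [f"G{j}" for j in range(30)],
                                  [f"c{i}" for i in range(240)], "SC")
        ds = cg.preprocess(ds, min_obs_per_gene=1, min_genes_per_cell=1)
        got = pseudo_label_cells(ds, n_types=3)
        assert got.provenance == "backend-clustering"
        assert ari(types[got.hc_indices], got.labels) >= 0.9

    def test_single_cell_type_one_cluster_all_retained(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5.0, size=(60, 20))
        ds = cg.ExpressionDataset(counts, [f"G{j}" for j in range(20)],
                                  [f"c{i}" for i in range(60)], "SC")
        ds = cg.preprocess(ds, min_obs_per_gene=1, min_genes_per_cell=1)
        out = pseudo_label_cells(ds, backend=lambda d, k: np.zeros(d.n_obs, dtype=int))
        assert len(out.hc_indices) == 60
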