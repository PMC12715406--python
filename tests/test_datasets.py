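import h5py
import numpy as np
import pytest

from coexgraph.datasets import (
    ExpressionDataset,
    align_genes,
    load_dataset,
    load_expression,
    preprocess,
    save_dataset,
)


def write_mtx_triplet(directory, counts, genes, barcodes):
    """10x-style MTX triplet (matrix is genes x cells on disk)."""
    directory.mkdir(parents=True, exist_ok=True)
    import scipy.io
    import scipy.sparse as sp

    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.csr_matrix(np.asarray(counts).T))
    (directory / "genes.tsv").write_text(
        "".join(f"ENS{i}\t{g}\n" for i, g in enumerate(genes)))
    (directory / "barcodes.tsv").write_text("".join(f"{b}\n" for b in barcodes))


class TestLoading:
    def test_mtx_round_trip(self, tmp_path):
        counts = np.array([[0, 1, 2], [3, 0, 0], [1, 1, 1], [0, 0, 5]])
        write_mtx_triplet(tmp_path, counts, ["A", "B", "C"], [f"s{i}" for i in range(4)])
        coords = "barcode,in_tissue,array_row,array_col,px_row,px_col\n" + "".join(
            f"s{i},1,{i},{i},0,0\n" for i in range(4))
        (tmp_path / "tissue_positions.csv").write_text(coords)
        ds = load_expression(tmp_path, "10x-mtx", "SRT")
        assert ds.counts.shape == (4, 3)
        np.testing.assert_array_equal(ds.counts, counts)
        assert ds.gene_ids == ["A", "B", "C"]
        np.testing.assert_array_equal(ds.coordinates[:, 0], np.arange(4))

    def test_srt_requires_coordinates(self, tmp_path):
        write_mtx_triplet(tmp_path, np.ones((2, 2), int), ["A", "B"], ["s0", "s1"])
        with pytest.raises(ValueError, match="coordinate"):
            load_expression(tmp_path, "10x-mtx", "SRT")
        # same matrix loads fine as single-cell data
        assert load_expression(tmp_path, "10x-mtx", "SC").n_obs == 2

    def test_csv_duplicate_gene_errors(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("obs,G1,G1\nc1,1,2\nc2,3,4\n")
        with pytest.raises(ValueError, match="G1"):
            load_expression(path, "csv", "SC")

    def test_10x_h5_fixture_reload(self, tmp_path):
        import scipy.sparse as sp

        counts = np.array([[0, 2, 1], [5, 0, 0]])  # cells x genes
        m = sp.csc_matrix(counts.T)  # 10x stores genes x cells, CSC
        path = tmp_path / "f.h5"
        with h5py.File(path, "w") as f:
            g = f.create_group("matrix")
            g.create_dataset("data", data=m.data.astype(np.int32))
            g.create_dataset("indices", data=m.indices.astype(np.int64))
            g.create_dataset("indptr", data=m.indptr.astype(np.int64))
            g.create_dataset("shape", data=np.array(m.shape, dtype=np.int32))
            g.create_dataset("barcodes", data=np.array([b"c1", b"c2"]))
            feat = g.create_group("features")
            feat.create_dataset("id", data=np.array([b"E1", b"E2", b"E3"]))
            feat.create_dataset("name", data=np.array([b"GA", b"GB", b"GC"]))
            feat.create_dataset("feature_type",
                                data=np.array([b"Gene Expression"] * 3))
            feat.create_dataset("genome", data=np.array([b"ref"] * 3))
        ds = load_expression(path, "10x-h5", "SC")
        np.testing.assert_array_equal(ds.counts, counts)

    def test_container_round_trip(self, tmp_path):
        ds = ExpressionDataset(
            counts=np.arange(12).reshape(3, 4),
            gene_ids=list("ABCD"), obs_ids=["s1", "s2", "s3"],
            modality="SRT", coordinates=np.arange(6).reshape(3, 2),
            labels=np.array(["x", "y", "x"]),
        )
        save_dataset(ds, tmp_path / "d.h5")
        back = load_dataset(tmp_path / "d.h5")
        np.testing.assert_array_equal(back.counts, ds.counts)
        assert back.gene_ids == ds.gene_ids
        np.testing.assert_array_equal(back.coordinates, ds.coordinates)
        np.testing.assert_array_equal(back.labels, ds.labels)

    def test_near_integer_counts_rounded_far_errors(self):
        with pytest.warns(UserWarning, match="rounding"):
            ds = ExpressionDataset(np.array([[1.0 + 1e-9]]), ["A"], ["c"], "SC")
        assert ds.counts.dtype.kind == "i"
        with pytest.raises(ValueError, match="non-integer"):
            ExpressionDataset(np.array([[1.5]]), ["A"], ["c"], "SC")


def make_sc(counts, genes=None):
    counts = np.asarray(counts)
    genes = genes or [f"G{j}" for j in range(counts.shape[1])]
    return ExpressionDataset(counts, genes, [f"c{i}" for i in range(counts.shape[0])], "SC")


class TestPreprocess:
    def test_gene_detection_threshold(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 5, size=(12, 4))
        counts[3:, 0] = 0  # gene g0 detected in only 3 cells
        ds = make_sc(counts, ["g0", "g1", "g2", "g3"])
        out = preprocess(ds, min_obs_per_gene=10, min_genes_per_cell=2)
        assert "g0" not in out.gene_ids and "g1" in out.gene_ids

    def test_cell_filter_applies_to_sc_but_not_srt(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 4, size=(15, 8))
        counts[0, 3:] = 0  # first obs detects only 3 genes
        sc = preprocess(make_sc(counts), min_obs_per_gene=1, min_genes_per_cell=5)
        assert sc.n_obs == 14
        srt = ExpressionDataset(counts, [f"G{j}" for j in range(8)],
                                [f"s{i}" for i in range(15)], "SRT",
                                coordinates=np.zeros((15, 2)) + np.arange(15)[:, None])
        out = preprocess(srt, min_obs_per_gene=1, min_genes_per_cell=5)
        assert out.n_obs == 15  # spatial integrity: no spot filtering

    def test_mito_and_ercc_removed(self):
        counts = np.ones((12, 3), dtype=int)
        ds = make_sc(counts, ["MT-CO1", "ERCC-0001", "ACTB"])
        out = preprocess(ds, min_obs_per_gene=1, min_genes_per_cell=1)
        assert out.gene_ids == ["ACTB"]

    def test_normalization_row_sums(self):
        rng = np.random.default_rng(2)
        ds = make_sc(rng.integers(0, 6, size=(15, 10)) + 1)
        out = preprocess(ds, min_obs_per_gene=1, min_genes_per_cell=1, target_sum=1e4)
        sums = np.expm1(out.normalized).sum(axis=1)
        np.testing.assert_allclose(sums, 1e4, rtol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        ds = make_sc(rng.integers(0, 3, size=(20, 12)))
        once = preprocess(ds, min_obs_per_gene=5, min_genes_per_cell=2)
        twice = preprocess(once, min_obs_per_gene=5, min_genes_per_cell=2)
        assert once.gene_ids == twice.gene_ids and once.obs_ids == twice.obs_ids
        np.testing.assert_allclose(once.normalized, twice.normalized)

    def test_gene_filter_matches_bruteforce_tally(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 2, size=(30, 20))
        ds = make_sc(counts)
        out = preprocess(ds, min_obs_per_gene=12, min_genes_per_cell=0)
        expected = [f"G{j}" for j in range(20) if (counts[:, j] > 0).sum() >= 12]
        assert out.gene_ids == expected

    def test_normalized_monotone_in_counts_within_observation(self):
        rng = np.random.default_rng(5)
        ds = make_sc(rng.integers(0, 9, size=(14, 9)))
        out = preprocess(ds, min_obs_per_gene=1, min_genes_per_cell=1)
        for i in range(out.n_obs):
            order = np.argsort(out.counts[i])
            assert np.all(np.diff(out.normalized[i][order]) >= 0)

    def test_srt_zero_library_spot_retained(self):
        counts = np.ones((12, 4), dtype=int)
        counts[0] = 0
        srt = ExpressionDataset(counts, list("ABCD"),
                                [f"s{i}" for i in range(12)], "SRT",
                                coordinates=np.column_stack([np.arange(12), np.zeros(12)]))
        out = preprocess(srt, min_obs_per_gene=1)
        assert out.n_obs == 12
        assert np.all(out.normalized[0] == 0)
        with pytest.raises(ValueError, match="zero library"):
            preprocess(make_sc(counts), min_obs_per_gene=1, min_genes_per_cell=0)


class TestAlignGenes:
    def _pair(self, srt_genes, sc_genes):
        n = 12
        rng = np.random.default_rng(0)
        srt = ExpressionDataset(rng.integers(1, 5, (n, len(srt_genes))), srt_genes,
                                [f"s{i}" for i in range(n)], "SRT",
                                coordinates=np.column_stack([np.arange(n), np.zeros(n)]))
        sc = make_sc(rng.integers(1, 5, (n, len(sc_genes))), sc_genes)
        return preprocess(srt, 1), preprocess(sc, 1, 1)

    def test_intersection_and_order(self):
        srt, sc = self._pair(["A", "B", "C"], ["B", "C", "D"])
        pair = align_genes(srt, sc)
        assert pair.shared_genes == ["B", "C"]
        assert pair.srt.gene_ids == pair.sc.gene_ids == ["B", "C"]

    def test_identical_sets(self):
        srt, sc = self._pair(["C", "A", "B"], ["A", "B", "C"])
        assert align_genes(srt, sc).shared_genes == ["A", "B", "C"]

    def test_case_sensitivity_switch(self):
        srt, sc = self._pair(["Gfap", "Aqp4"], ["GFAP", "XYZ"])
        with pytest.raises(ValueError, match="no shared genes"):
            align_genes(srt, sc)
        pair = align_genes(srt, sc, case_insensitive=True)
        assert pair.shared_genes == ["Gfap"]
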