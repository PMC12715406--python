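"""Expression containers and I/O for paired spatial / single-cell data.

The two modalities are held in a small common container, :class:`ExpressionDataset`,
carrying a raw count matrix, a library-size-normalized log layer, gene/observation
identifiers, and modality-specific metadata (2D spot coordinates for spatial data,
optional categorical labels for either modality).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

Modality = Literal["SRT", "SC"]

_MITO_ERCC_DEFAULT = r"^(MT-|mt-|ERCC-)"


@dataclass
class ExpressionDataset:
    """One modality's expression data.

    Attributes
    ----------
    counts
        Nonnegative integer matrix, observations x genes (dense ``ndarray``).
    gene_ids, obs_ids
        Unique, ordered identifiers along the two axes.
    modality
        ``"SRT"`` (spots with coordinates) or ``"SC"`` (cells).
    coordinates
        (n_obs, 2) array of spot positions; required iff modality is SRT.
    labels
        Optional per-observation categorical labels (domains / cell types).
    normalized
        Library-size-normalized, log1p-transformed layer; filled by
        :func:`preprocess` (``None`` on raw data).
    """

    counts: np.ndarray
    gene_ids: list[str]
    obs_ids: list[str]
    modality: Modality
    coordinates: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    normalized: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2D (observations x genes)")
        n_obs, n_genes = self.counts.shape
        if len(self.obs_ids) != n_obs or len(self.gene_ids) != n_genes:
            raise ValueError("id lengths do not match counts shape")
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValueError(f"duplicated gene id: {dup!r}")
        dup = _first_duplicate(self.obs_ids)
        if dup is not None:
            raise ValueError(f"duplicated observation id: {dup!r}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if np.max(np.abs(self.counts - rounded)) > 1e-6:
                raise ValueError("counts contain non-integer values")
            warnings.warn("non-integer counts within 1e-6 of integers; rounding")
            self.counts = rounded.astype(np.int64)
        if self.modality == "SRT":
            if self.coordinates is None:
                raise ValueError("SRT dataset requires spot coordinates")
            self.coordinates = np.asarray(self.coordinates, dtype=float)
            if self.coordinates.shape != (n_obs, 2):
                raise ValueError("coordinates must be (n_obs, 2)")
        elif self.coordinates is not None:
            raise ValueError("coordinates are only valid for SRT data")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != n_obs:
                raise ValueError("one label per observation required")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)
            if self.normalized.shape != self.counts.shape:
                raise ValueError("normalized layer must match counts shape")

    @property
    def n_obs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        """Return a copy restricted to ``gene_ids`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        cols = np.array([index[g] for g in gene_ids], dtype=int)
        return replace(
            self,
            counts=self.counts[:, cols],
            gene_ids=list(gene_ids),
            normalized=None if self.normalized is None else self.normalized[:, cols],
        )

    def subset_obs(self, mask_or_idx: np.ndarray) -> "ExpressionDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            counts=self.counts[idx],
            obs_ids=[self.obs_ids[i] for i in idx],
            coordinates=None if self.coordinates is None else self.coordinates[idx],
            labels=None if self.labels is None else self.labels[idx],
            normalized=None if self.normalized is None else self.normalized[idx],
        )


@dataclass
class PairedDatasets:
    """A spatial dataset and a single-cell dataset on a shared gene namespace."""

    srt: ExpressionDataset
    sc: ExpressionDataset
    shared_genes: list[str]

    def __post_init__(self) -> None:
        for ds in (self.srt, self.sc):
            missing = set(self.shared_genes) - set(ds.gene_ids)
            if missing:
                raise ValueError(f"shared genes missing from {ds.modality}: {sorted(missing)[:5]}")


def _first_duplicate(items: Sequence[str]) -> Optional[str]:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def load_expression(
    path: str | Path,
    format: Literal["10x-mtx", "10x-h5", "csv"],
    modality: Modality,
    coordinates_path: str | Path | None = None,
) -> ExpressionDataset:
    """Load raw counts from a standard format; no filtering is applied.

    For SRT data a coordinate table must be locatable: either
    ``coordinates_path`` or a ``tissue_positions*.csv`` file next to the
    matrix (10x conventions; header dialect auto-detected).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "10x-mtx":
        counts, gene_ids, obs_ids = _read_10x_mtx(path)
    elif format == "10x-h5":
        counts, gene_ids, obs_ids = _read_10x_h5(path)
    elif format == "csv":
        with open(path) as fh:  # pandas silently renames duplicate columns
            header = fh.readline().rstrip("\n").split(",")[1:]
        dup = _first_duplicate(header)
        if dup is not None:
            raise ValueError(f"duplicated gene id in {path.name}: {dup!r}")
        df = pd.read_csv(path, index_col=0)
        counts = df.to_numpy()
        gene_ids = [str(g) for g in df.columns]
        obs_ids = [str(o) for o in df.index]
    else:
        raise ValueError(f"unknown format: {format}")

    coordinates = None
    if modality == "SRT":
        coord_file = Path(coordinates_path) if coordinates_path else _find_positions_file(path)
        if coord_file is None:
            raise ValueError("SRT data requires a tissue-positions/coordinate table")
        coordinates = _read_positions(coord_file, obs_ids)
    return ExpressionDataset(
        counts=counts, gene_ids=gene_ids, obs_ids=obs_ids, modality=modality,
        coordinates=coordinates,
    )


def _read_10x_mtx(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    """10x MTX triplet directory: matrix.mtx[.gz], features/genes.tsv[.gz], barcodes.tsv[.gz]."""
    directory = path if path.is_dir() else path.parent

    def _locate(stems: list[str]) -> Path:
        for stem in stems:
            for suffix in ("", ".gz"):
                cand = directory / f"{stem}{suffix}"
                if cand.exists():
                    return cand
        raise FileNotFoundError(f"none of {stems} found under {directory}")

    mat = scipy.io.mmread(_locate(["matrix.mtx"]))
    feat = pd.read_csv(_locate(["features.tsv", "genes.tsv"]), sep="\t", header=None)
    barcodes = pd.read_csv(_locate(["barcodes.tsv"]), sep="\t", header=None)
    # features file: column 0 = id, column 1 = symbol (when present)
    symbol_col = 1 if feat.shape[1] > 1 else 0
    gene_ids = [str(g) for g in feat.iloc[:, symbol_col]]
    obs_ids = [str(b) for b in barcodes.iloc[:, 0]]
    counts = np.asarray(sp.csr_matrix(mat).T.todense())  # 10x stores genes x cells
    return counts, gene_ids, obs_ids


def _read_10x_h5(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    import scanpy as scpy

    adata = scpy.read_10x_h5(path)
    counts = adata.X
    if sp.issparse(counts):
        counts = np.asarray(counts.todense())
    return counts, [str(g) for g in adata.var_names], [str(o) for o in adata.obs_names]


def _find_positions_file(path: Path) -> Optional[Path]:
    directory = path if path.is_dir() else path.parent
    for name in ("tissue_positions.csv", "tissue_positions_list.csv", "coordinates.csv"):
        for base in (directory, directory / "spatial"):
            cand = base / name
            if cand.exists():
                return cand
    return None


def _read_positions(path: Path, obs_ids: Sequence[str]) -> np.ndarray:
    """Read a tissue-positions table; header vs headerless dialect auto-detected."""
    with open(path) as fh:
        first = fh.readline()
    has_header = "barcode" in first.lower() or "array_row" in first.lower()
    df = pd.read_csv(path, header=0 if has_header else None)
    if has_header:
        cols = {c.lower(): c for c in df.columns}
        bc = cols.get("barcode", df.columns[0])
        row_col = cols.get("array_row", df.columns[-4])
        col_col = cols.get("array_col", df.columns[-3])
        table = df.set_index(df[bc].astype(str))[[row_col, col_col]]
    else:
        # legacy order: barcode, in_tissue, array_row, array_col, px_row, px_col
        table = df.set_index(df[0].astype(str))[[2, 3]]
    missing = [o for o in obs_ids if o not in table.index]
    if missing:
        raise ValueError(f"coordinates missing for observations, e.g. {missing[:3]}")
    return table.loc[list(obs_ids)].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    ds: ExpressionDataset,
    min_obs_per_gene: int = 10,
    min_genes_per_cell: int = 200,
    target_sum: float = 1e4,
    exclude_gene_regex: str = _MITO_ERCC_DEFAULT,
) -> ExpressionDataset:
    """Filter genes/cells and attach the normalized layer.

    Mitochondrial ("MT-"/"mt-") and ERCC spike-in genes are removed, then genes
    detected in fewer than ``min_obs_per_gene`` observations. Single-cell data
    additionally drop cells with fewer than ``min_genes_per_cell`` detected
    genes; spatial data never drop spots, preserving the spatial lattice.
    The normalized layer is ``log(1 + count * target_sum / library_size)``.
    Idempotent: a second application is a no-op.
    """
    pattern = re.compile(exclude_gene_regex)
    keep = np.array([pattern.match(g) is None for g in ds.gene_ids])
    counts = ds.counts[:, keep]
    gene_ids = [g for g, k in zip(ds.gene_ids, keep) if k]

    detected = (counts > 0).sum(axis=0)
    keep_gene = detected >= min_obs_per_gene
    if not np.any(keep_gene):
        raise ValueError("all genes removed by filtering")
    counts = counts[:, keep_gene]
    gene_ids = [g for g, k in zip(gene_ids, keep_gene) if k]

    obs_idx = np.arange(ds.n_obs)
    if ds.modality == "SC":
        genes_per_cell = (counts > 0).sum(axis=1)
        keep_obs = genes_per_cell >= min_genes_per_cell
        counts = counts[keep_obs]
        obs_idx = obs_idx[keep_obs]
        if counts.shape[0] == 0:
            raise ValueError("all cells removed by filtering")

    libsize = counts.sum(axis=1).astype(float)
    if ds.modality == "SC" and np.any(libsize == 0):
        raise ValueError("single cells with zero library size after filtering")
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(libsize[:, None] > 0, counts * (target_sum / np.maximum(libsize, 1))[:, None], 0.0)
    normalized = np.log1p(scaled)

    return ExpressionDataset(
        counts=counts,
        gene_ids=gene_ids,
        obs_ids=[ds.obs_ids[i] for i in obs_idx],
        modality=ds.modality,
        coordinates=None if ds.coordinates is None else ds.coordinates[obs_idx],
        labels=None if ds.labels is None else ds.labels[obs_idx],
        normalized=normalized,
    )


def align_genes(
    srt: ExpressionDataset,
    sc: ExpressionDataset,
    case_insensitive: bool = False,
) -> PairedDatasets:
    """Restrict both modalities to their shared genes, lexicographically ordered.

    With ``case_insensitive=True``, symbols differing only by case (e.g. mouse
    "Gfap" vs human "GFAP") are matched; the SRT spelling is kept.
    """
    if case_insensitive:
        sc_map = {g.lower(): g for g in sc.gene_ids}
        shared = sorted(g for g in srt.gene_ids if g.lower() in sc_map)
        sc_genes = [sc_map[g.lower()] for g in shared]
    else:
        sc_set = set(sc.gene_ids)
        shared = sorted(g for g in srt.gene_ids if g in sc_set)
        sc_genes = shared
    if not shared:
        raise ValueError("no shared genes between modalities")
    srt_sub = srt.subset_genes(shared)
    sc_sub = sc.subset_genes(sc_genes)
    sc_sub.gene_ids = list(shared)
    # re-derive normalized layers on the restricted gene set is NOT done: the
    # normalization denominators come from the full library, matching practice.
    if srt.normalized is not None:
        srt_sub.normalized = srt.normalized[:, [srt.gene_ids.index(g) for g in shared]]
    if sc.normalized is not None:
        idx = {g: i for i, g in enumerate(sc.gene_ids)}
        sc_sub.normalized = sc.normalized[:, [idx[g] for g in sc_genes]]
    return PairedDatasets(srt=srt_sub, sc=sc_sub, shared_genes=list(shared))


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def save_dataset(ds: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset to an HDF5 container with 'counts' and 'normalized' layers."""
    with h5py.File(path, "w") as f:
        f.create_dataset("layers/counts", data=ds.counts)
        if ds.normalized is not None:
            f.create_dataset("layers/normalized", data=ds.normalized)
        f.create_dataset("gene_ids", data=np.array(ds.gene_ids, dtype="S"))
        f.create_dataset("obs_ids", data=np.array(ds.obs_ids, dtype="S"))
        f.attrs["modality"] = ds.modality
        if ds.coordinates is not None:
            f.create_dataset("coordinates", data=ds.coordinates)
        if ds.labels is not None:
            f.create_dataset("labels", data=np.array(ds.labels, dtype="S"))


def load_dataset(path: str | Path) -> ExpressionDataset:
    with h5py.File(path, "r") as f:
        kwargs = dict(
            counts=f["layers/counts"][...],
            gene_ids=[g.decode() for g in f["gene_ids"][...]],
            obs_ids=[o.decode() for o in f["obs_ids"][...]],
            modality=f.attrs["modality"],
        )
        if "layers/normalized" in f:
            kwargs["normalized"] = f["layers/normalized"][...]
        if "coordinates" in f:
            kwargs["coordinates"] = f["coordinates"][...]
        if "labels" in f:
            kwargs["labels"] = np.array([x.decode() for x in f["labels"][...]])
    return ExpressionDataset(**kwargs)
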