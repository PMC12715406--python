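"""Evaluation metrics: Davies-Bouldin under gene-level distance models,
adjusted Rand index, normalized mutual information, and the neighbor-voting
gene co-function AUC.

The Davies-Bouldin index is computed with two domain-specific gene-gene
distances: Pearson distance (1 - correlation; co-expression across cells) and
a spatially weighted Euclidean distance between rasterized spatial expression
maps, where the quadratic-form weight matrix is a Gaussian kernel of raster
cell locations (spatial coherence across tissue domains).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.special import comb


# ---------------------------------------------------------------------------
# Distance models
# ---------------------------------------------------------------------------

def pearson_distance(expr: np.ndarray) -> np.ndarray:
    """Gene-gene distance 1 - rho over observations (rows obs, cols genes).
    Zero-variance genes get rho := 0, distance 1 to all others."""
    x = np.asarray(expr, dtype=float)
    sd = x.std(axis=0)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} zero-variance genes; correlation set to 0")
    z = (x - x.mean(axis=0)) / np.where(flat, 1.0, sd)
    rho = z.T @ z / x.shape[0]
    rho[flat, :] = 0.0
    rho[:, flat] = 0.0
    np.fill_diagonal(rho, 1.0)
    return 1.0 - rho


def rasterize(
    expr: np.ndarray, coordinates: np.ndarray, raster_shape: tuple[int, int]
) -> np.ndarray:
    """Bin spots to the nearest raster cell, averaging multiple spots per cell;
    empty cells are zero. Returns (n_genes, nx*ny) flattened rasters."""
    nx, ny = raster_shape
    if nx < 1 or ny < 1 or coordinates.shape[0] == 0:
        raise ValueError("empty raster")
    coords = np.asarray(coordinates, dtype=float)
    lo = coords.min(axis=0)
    span = np.maximum(coords.max(axis=0) - lo, 1e-12)
    gx = np.minimum((nx * (coords[:, 0] - lo[0]) / span[0]).astype(int), nx - 1)
    gy = np.minimum((ny * (coords[:, 1] - lo[1]) / span[1]).astype(int), ny - 1)
    cell = gx * ny + gy
    n_genes = expr.shape[1]
    sums = np.zeros((nx * ny, n_genes))
    counts = np.zeros(nx * ny)
    np.add.at(sums, cell, expr)
    np.add.at(counts, cell, 1)
    with np.errstate(invalid="ignore"):
        raster = np.where(counts[:, None] > 0, sums / np.maximum(counts, 1)[:, None], 0.0)
    return raster.T


def gaussian_raster_kernel(
    raster_shape: tuple[int, int], bandwidth: float = 1.5, truncate: float = 3.0
) -> sp.csr_matrix:
    """Sparse Gaussian kernel over raster cell locations,
    W_ab = exp(-||a-b||^2 / (2 sigma^2)), truncated to 0 beyond ``truncate``
    sigma (the dense cell x cell matrix is infeasible at scale)."""
    nx, ny = raster_shape
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    loc = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    cutoff = truncate * bandwidth
    from scipy.spatial import cKDTree

    tree = cKDTree(loc)
    pairs = tree.sparse_distance_matrix(tree, cutoff, output_type="coo_matrix")
    vals = np.exp(-pairs.data**2 / (2 * bandwidth**2))
    W = sp.csr_matrix((vals, (pairs.row, pairs.col)), shape=(len(loc), len(loc)))
    return W


def weighted_euclid_distance(
    expr_srt: np.ndarray,
    coordinates: np.ndarray,
    raster_shape: tuple[int, int],
    bandwidth: float = 1.5,
    W: Optional[sp.spmatrix] = None,
) -> np.ndarray:
    """Gene-gene distance sqrt((x_p - x_q)^T W (x_p - x_q)) between flattened
    spatial rasters; W identity recovers plain Euclidean distance."""
    rasters = rasterize(expr_srt, coordinates, raster_shape)
    if W is None:
        W = gaussian_raster_kernel(raster_shape, bandwidth)
    n = rasters.shape[0]
    WX = np.asarray((W @ rasters.T))  # (cells, genes)
    G = rasters @ WX                  # x_p^T W x_q
    d2 = np.diag(G)[:, None] + np.diag(G)[None, :] - G - G.T
    d2 = np.maximum((d2 + d2.T) / 2, 0.0)
    out = np.sqrt(d2)
    np.fill_diagonal(out, 0.0)
    return out


@dataclass
class DistanceModel:
    """A gene-gene distance family usable both pairwise and between centroids.

    ``kind``: "euclid" (plain), "pearson" (1 - correlation of the point
    vectors), or "weighted_euclid" (quadratic form with a Gaussian raster
    kernel ``W``; points must be flattened rasters).
    """

    kind: str = "euclid"
    W: Optional[sp.spmatrix] = None

    def pairwise(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.kind == "pearson":
            return pearson_distance(X.T)
        if self.kind == "weighted_euclid":
            if self.W is None:
                raise ValueError("weighted_euclid requires the kernel W")
            WX = np.asarray(self.W @ X.T)
            G = X @ WX
            d2 = np.diag(G)[:, None] + np.diag(G)[None, :] - G - G.T
            return np.sqrt(np.maximum((d2 + d2.T) / 2, 0.0))
        diff = X[:, None, :] - X[None, :, :]
        return np.sqrt((diff**2).sum(-1))

    def between(self, u: np.ndarray, v: np.ndarray) -> float:
        return float(self.pairwise(np.vstack([u, v]))[0, 1])


# ---------------------------------------------------------------------------
# Davies-Bouldin
# ---------------------------------------------------------------------------

def db_index(
    assignment: np.ndarray,
    points: np.ndarray,
    distance: Optional[DistanceModel] = None,
) -> float:
    """Davies-Bouldin index: mean over clusters of the worst
    (d_i + d_j) / d(centroid_i, centroid_j) ratio.

    d_i is the average pairwise distance within cluster i (the 2/(n(n-1))
    normalization); d(i, j) is the model distance between cluster centroids
    (mean point vectors). Singleton clusters get d_i = 0 with a warning;
    identical centroids yield an infinite ratio that dominates the score.
    """
    labels = np.asarray(assignment)
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters")
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    model = distance or DistanceModel("euclid")
    full = model.pairwise(pts)

    intra, centroids = {}, {}
    for c in ids:
        idx = np.flatnonzero(labels == c)
        centroids[c] = pts[idx].mean(axis=0)
        if idx.size < 2:
            warnings.warn(f"singleton cluster {c}; intra-distance set to 0")
            intra[c] = 0.0
        else:
            block = full[np.ix_(idx, idx)]
            intra[c] = block.sum() / (idx.size * (idx.size - 1))

    cent = model.pairwise(np.vstack([centroids[c] for c in ids]))
    total = 0.0
    for a, ca in enumerate(ids):
        worst = 0.0
        for b, cb in enumerate(ids):
            if a == b:
                continue
            dab = cent[a, b]
            ratio = np.inf if dab == 0 else (intra[ca] + intra[cb]) / dab
            worst = max(worst, ratio)
        total += worst
    return float(total / len(ids))


# ---------------------------------------------------------------------------
# ARI / NMI (contingency-table definitions)
# ---------------------------------------------------------------------------

def ari(labels_true, labels_pred) -> float:
    """Adjusted Rand index from the contingency table."""
    t = np.asarray(labels_true)
    p = np.asarray(labels_pred)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    n = t.shape[0]
    _, ti = np.unique(t, return_inverse=True)
    _, pi = np.unique(p, return_inverse=True)
    table = np.zeros((ti.max() + 1, pi.max() + 1))
    np.add.at(table, (ti, pi), 1)
    sum_ij = comb(table, 2).sum()
    a = comb(table.sum(axis=1), 2).sum()
    b = comb(table.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = a * b / total
    max_index = (a + b) / 2
    if max_index == expected:
        return 1.0  # both labelings trivially identical partitions
    return float((sum_ij - expected) / (max_index - expected))


def _label_entropy(x: np.ndarray) -> float:
    _, counts = np.unique(x, return_counts=True)
    pr = counts / counts.sum()
    return float(-(pr * np.log(pr)).sum())


def nmi(labels_true, labels_pred) -> float:
    """NMI = 2 MI(L~, L) / (H(L~) + H(L)); 1 when both are a single identical
    class (0/0 convention)."""
    t = np.asarray(labels_true)
    p = np.asarray(labels_pred)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    ht, hp = _label_entropy(t), _label_entropy(p)
    if ht + hp == 0:
        return 1.0
    _, ti = np.unique(t, return_inverse=True)
    _, pi = np.unique(p, return_inverse=True)
    table = np.zeros((ti.max() + 1, pi.max() + 1))
    np.add.at(table, (ti, pi), 1)
    joint = table / table.sum()
    outer = joint.sum(axis=1, keepdims=True) * joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / outer[nz])).sum())
    return float(2 * mi / (ht + hp))


# ---------------------------------------------------------------------------
# Neighbor-voting co-function AUC
# ---------------------------------------------------------------------------

def double_center_similarity(distance_table: np.ndarray) -> np.ndarray:
    """S = -1/2 (I - M/d) D (I - M/d), with M the all-ones matrix: the classic
    conversion of a distance table into an inner-product-like similarity."""
    D = np.asarray(distance_table, dtype=float)
    d = D.shape[0]
    J = np.eye(d) - np.ones((d, d)) / d
    return -0.5 * J @ D @ J


def _auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with midranks for ties."""
    from scipy.stats import rankdata

    pos = truth.astype(bool)
    n1, n0 = pos.sum(), (~pos).sum()
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def cofunction_auc(
    delta_pearson: np.ndarray,
    delta_euclid: np.ndarray,
    annotations: np.ndarray,
    w: float = 0.5,
    n_folds: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Per-term neighbor-voting AUC under cross-validation.

    Distance tables are double-centered into similarities (the single-cell
    table enters through the entrywise absolute value of the Pearson
    distances), fused with weight ``w`` on the spatial similarity, and each
    fold masks one third of the genes' annotation rows; a masked gene's term
    membership is predicted as p_tj = sum_i S_ti A_ij / sum_i S_ti and scored
    by AUC against the held-out truth, averaged over folds.
    """
    A = np.asarray(annotations, dtype=float)
    if not np.isin(A, (0, 1)).all():
        raise ValueError("annotation table must be binary")
    d, q = A.shape
    S_sc = double_center_similarity(np.abs(np.asarray(delta_pearson)))
    S_srt = double_center_similarity(np.asarray(delta_euclid))
    S = w * S_srt + (1 - w) * S_sc

    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(np.arange(d) % n_folds)
    aucs = np.full((n_folds, q), np.nan)
    for f in range(n_folds):
        test = fold_of == f
        A_masked = A.copy()
        A_masked[test, :] = 0.0
        denom = S.sum(axis=1)
        denom = np.where(denom == 0, 1.0, denom)
        P = (S @ A_masked) / denom[:, None]
        for j in range(q):
            truth = A[test, j]
            if truth.min() == truth.max():
                warnings.warn(f"term {j} has degenerate held-out truth in fold {f}; skipped")
                continue
            aucs[f, j] = _auc(P[test, j], truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(aucs, axis=0)
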