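"""Stage I: highly confident (HC) pseudo-labels for spatial spots and cells.

Spots are first clustered into spatial domains by any injected backend (or a
default community-detection backend on a joint expression/spatial graph).
Peripheral spots — those whose neighbor labels are heterogeneous (high
entropy) or predominantly different from their own — are discarded. Each
domain's remaining spots form connected subgraphs; small islands are dropped,
and within each subgraph the graph center (minimum-eccentricity vertices,
hop distances by all-pairs shortest paths) anchors the HC selection: spots
closer to the center than 0.6x the subgraph radius are trusted to carry the
domain label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, shortest_path

from .datasets import ExpressionDataset

ClusteringBackend = Callable[[ExpressionDataset, Optional[int]], np.ndarray]


@dataclass
class SubgraphRecord:
    domain: object
    vertices: np.ndarray          # global spot indices
    centers: np.ndarray           # global indices of the center set
    radius: int
    eccentricities: np.ndarray    # aligned with vertices
    hc: np.ndarray                # global indices of selected HC spots


@dataclass
class HCPseudoLabels:
    """Retained observation indices with their pseudo-labels."""

    hc_indices: np.ndarray
    labels: np.ndarray            # one label per retained index
    provenance: str               # "user" or "backend-clustering"
    records: list[SubgraphRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.hc_indices) != len(self.labels):
            raise ValueError("one label per retained index required")


# ---------------------------------------------------------------------------
# Initial clustering backends
# ---------------------------------------------------------------------------

def _pca(X: np.ndarray, n_components: int, seed: int = 0) -> np.ndarray:
    from sklearn.decomposition import PCA

    n_components = min(n_components, min(X.shape) - 1)
    return PCA(n_components=n_components, random_state=seed).fit_transform(X)


def _knn_edges(X: np.ndarray, k: int) -> set[tuple[int, int]]:
    from sklearn.neighbors import NearestNeighbors

    k = min(k, X.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    edges = set()
    for i, row in enumerate(idx):
        for j in row[1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    return edges


def _leiden_partition(
    n: int, edges: set[tuple[int, int]], n_clusters: Optional[int], seed: int
) -> np.ndarray:
    import igraph
    import leidenalg

    graph = igraph.Graph(n=n, edges=sorted(edges))

    def run(resolution: float) -> np.ndarray:
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        return np.array(part.membership)

    if n_clusters is None:
        return run(1.0)
    # bisection on the resolution to hit the requested cluster count
    lo, hi = 1e-4, 10.0
    best, best_gap = run(1.0), None
    for _ in range(25):
        mid = np.sqrt(lo * hi)
        labels = run(mid)
        k = len(np.unique(labels))
        gap = abs(k - n_clusters)
        if best_gap is None or gap < best_gap:
            best, best_gap = labels, gap
        if k == n_clusters:
            return labels
        if k < n_clusters:
            lo = mid
        else:
            hi = mid
    return best


def default_spatial_backend(
    ds: ExpressionDataset, n_domains: Optional[int] = None,
    n_pcs: int = 30, k_expr: int = 15, seed: int = 0,
) -> np.ndarray:
    """Community detection on the union of an expression-PCA kNN graph and the
    spatial-neighbor graph."""
    X = ds.normalized if ds.normalized is not None else np.log1p(ds.counts.astype(float))
    pcs = _pca(X, n_pcs, seed)
    edges = _knn_edges(pcs, k_expr)
    edges |= {
        (min(i, j), max(i, j))
        for i, j in zip(*np.nonzero(spatial_adjacency(ds.coordinates).toarray()))
        if i < j
    }
    return _leiden_partition(ds.n_obs, edges, n_domains, seed)


def default_cell_backend(
    ds: ExpressionDataset, n_types: Optional[int] = None,
    n_pcs: int = 30, k: int = 15, seed: int = 0,
) -> np.ndarray:
    """Community detection on an expression-PCA kNN graph (cells)."""
    X = ds.normalized if ds.normalized is not None else np.log1p(ds.counts.astype(float))
    pcs = _pca(X, n_pcs, seed)
    return _leiden_partition(ds.n_obs, _knn_edges(pcs, k), n_types, seed)


def spatial_adjacency(coordinates: np.ndarray, max_neighbors: int = 6) -> sp.csr_matrix:
    """Symmetric spot-neighbor graph from coordinates.

    Spots are linked to every other spot at (approximately) the minimal
    positive center-to-center distance, capped at ``max_neighbors``; on a
    Visium-style array-row/col lattice this yields the usual hexagonal (or
    square) neighbor structure.
    """
    from sklearn.neighbors import NearestNeighbors

    n = coordinates.shape[0]
    k = min(max_neighbors + 1, n)
    nn = NearestNeighbors(n_neighbors=k).fit(coordinates)
    dist, idx = nn.kneighbors(coordinates)
    positive = dist[:, 1:]
    cutoff = np.min(positive[positive > 0]) * 1.3 if np.any(positive > 0) else 0.0
    rows, cols = [], []
    for i in range(n):
        for d, j in zip(dist[i, 1:], idx[i, 1:]):
            if 0 < d <= cutoff:
                rows.append(i)
                cols.append(int(j))
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    adj = ((adj + adj.T) > 0).astype(np.int8)
    return sp.csr_matrix(adj)


def initial_domains(
    srt: ExpressionDataset,
    backend: Optional[ClusteringBackend] = None,
    n_domains: Optional[int] = None,
) -> np.ndarray:
    """One domain label per spot from the injected (or default) backend."""
    if srt.labels is not None and backend is None:
        return np.asarray(srt.labels)
    backend = backend or default_spatial_backend
    labels = np.asarray(backend(srt, n_domains))
    if labels.shape[0] != srt.n_obs:
        raise ValueError("backend returned wrong-length labels")
    return labels


# ---------------------------------------------------------------------------
# Entropy filtering
# ---------------------------------------------------------------------------

def neighbor_label_entropy(neighbor_labels: Sequence) -> float:
    """Shannon entropy (bits) of the label distribution among a spot's neighbors."""
    labels = np.asarray(neighbor_labels)
    if labels.size == 0:
        return float("nan")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _entropies(labels: np.ndarray, adjacency: sp.spmatrix) -> np.ndarray:
    adj = sp.csr_matrix(adjacency)
    return np.array([
        neighbor_label_entropy(labels[adj.indices[adj.indptr[i]: adj.indptr[i + 1]]])
        for i in range(labels.shape[0])
    ])


def filter_peripheral(labels: np.ndarray, adjacency: sp.spmatrix) -> np.ndarray:
    """Indices of spots surviving the entropy + majority-label filter.

    The entropy threshold e is the median of the positive neighbor-label
    entropies (all spots retained when every entropy is zero). A spot is kept
    iff its entropy is <= e AND a strict majority of its neighbors share its
    own label. Isolated spots (no neighbors) are treated as peripheral.
    """
    labels = np.asarray(labels)
    adj = sp.csr_matrix(adjacency)
    H = _entropies(labels, adj)
    finite = H[~np.isnan(H)]
    positive = finite[finite > 0]
    e = np.median(positive) if positive.size else np.inf

    keep = []
    for i in range(labels.shape[0]):
        neigh = adj.indices[adj.indptr[i]: adj.indptr[i + 1]]
        if neigh.size == 0 or np.isnan(H[i]) or H[i] > e:
            continue
        if 2 * np.sum(labels[neigh] == labels[i]) > neigh.size:
            keep.append(i)
    return np.array(keep, dtype=int)


# ---------------------------------------------------------------------------
# Subgraphs, centers, HC selection
# ---------------------------------------------------------------------------

def domain_subgraphs(
    retained: np.ndarray,
    labels: np.ndarray,
    adjacency: sp.spmatrix,
    min_size: int = 6,
) -> list[tuple[object, np.ndarray]]:
    """Connected components of retained same-domain spots, dropping islands
    smaller than ``min_size`` (the lattice neighbor count: 6 for Visium hex)."""
    retained = np.asarray(retained)
    adj = sp.csr_matrix(adjacency)
    out: list[tuple[object, np.ndarray]] = []
    for dom in sorted({str(x) for x in np.asarray(labels)[retained]}):
        verts = retained[np.asarray([str(x) for x in np.asarray(labels)[retained]]) == dom]
        sub = adj[np.ix_(verts, verts)]
        n_comp, comp = connected_components(sub, directed=False)
        for c in range(n_comp):
            members = verts[comp == c]
            if members.size >= min_size:
                out.append((dom, members))
    return out


def center_radius(sub_adj: sp.spmatrix) -> tuple[np.ndarray, int, np.ndarray]:
    """Graph center of a connected subgraph by all-pairs hop distances.

    Returns (center vertex positions, radius, per-vertex eccentricities);
    positions are local indices into the subgraph.
    """
    dist = shortest_path(sp.csr_matrix(sub_adj), unweighted=True, directed=False)
    if np.isinf(dist).any():
        raise ValueError("subgraph is disconnected; pass connected components")
    ecc = dist.max(axis=1)
    radius = int(ecc.min())
    centers = np.flatnonzero(ecc == radius)
    return centers, radius, ecc


def select_hc(
    sub_adj: sp.spmatrix,
    centers: np.ndarray,
    radius: int,
    fraction: float = 0.6,
) -> np.ndarray:
    """Local indices of HC spots: distance-to-center strictly below
    ``fraction * radius``. Center vertices are always included, so singleton
    components (radius 0) still yield HC spots."""
    dist = shortest_path(sp.csr_matrix(sub_adj), unweighted=True, directed=False)
    d_to_center = dist[:, centers].min(axis=1)
    selected = d_to_center < fraction * radius
    selected[centers] = True
    return np.flatnonzero(selected)


def hc_spots(
    srt: ExpressionDataset,
    labels: Optional[np.ndarray] = None,
    backend: Optional[ClusteringBackend] = None,
    n_domains: Optional[int] = None,
    fraction: float = 0.6,
    min_subgraph_size: int = 6,
) -> HCPseudoLabels:
    """Full Stage-I pipeline for spots: initial domains -> peripheral filter ->
    per-domain subgraphs -> graph centers -> HC selection."""
    provenance = "user"
    if labels is None:
        provenance = "user" if (srt.labels is not None and backend is None) else "backend-clustering"
        labels = initial_domains(srt, backend=backend, n_domains=n_domains)
    labels = np.asarray(labels)
    adj = spatial_adjacency(srt.coordinates)
    retained = filter_peripheral(labels, adj)
    subs = domain_subgraphs(retained, labels, adj, min_size=min_subgraph_size)

    records, hc_idx, hc_lab = [], [], []
    for dom, verts in subs:
        sub = adj[np.ix_(verts, verts)]
        centers, radius, ecc = center_radius(sub)
        local_hc = select_hc(sub, centers, radius, fraction)
        records.append(SubgraphRecord(
            domain=dom, vertices=verts, centers=verts[centers],
            radius=radius, eccentricities=ecc, hc=verts[local_hc],
        ))
        hc_idx.extend(verts[local_hc].tolist())
        hc_lab.extend([dom] * local_hc.size)
    return HCPseudoLabels(
        hc_indices=np.array(hc_idx, dtype=int),
        labels=np.array(hc_lab),
        provenance=provenance,
        records=records,
    )


def pseudo_label_cells(
    sc: ExpressionDataset,
    backend: Optional[ClusteringBackend] = None,
    n_types: Optional[int] = None,
    k_graph: int = 15,
) -> HCPseudoLabels:
    """HC pseudo-labels for cells.

    With user labels present, all cells pass through unchanged. Otherwise
    cells are clustered (default: community detection on an expression-PCA
    kNN graph) and only high-confidence cells are retained: those whose
    neighbor-label entropy in the kNN graph does not exceed the median
    positive entropy and whose neighbors mostly agree with their own label —
    the single-cell mirror of the spot rule.
    """
    if sc.labels is not None and backend is None:
        return HCPseudoLabels(
            hc_indices=np.arange(sc.n_obs),
            labels=np.asarray(sc.labels),
            provenance="user",
        )
    backend = backend or default_cell_backend
    labels = np.asarray(backend(sc, n_types))
    if labels.shape[0] != sc.n_obs:
        raise ValueError("backend returned wrong-length labels")
    if len(np.unique(labels)) == 1:
        return HCPseudoLabels(
            hc_indices=np.arange(sc.n_obs), labels=labels,
            provenance="backend-clustering",
        )
    X = sc.normalized if sc.normalized is not None else np.log1p(sc.counts.astype(float))
    pcs = _pca(X, 30)
    edges = _knn_edges(pcs, k_graph)
    rows = [i for i, j in edges] + [j for i, j in edges]
    cols = [j for i, j in edges] + [i for i, j in edges]
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(sc.n_obs, sc.n_obs))
    retained = filter_peripheral(labels, adj)
    if retained.size == 0:
        warnings.warn("entropy filter removed every cell; retaining all")
        retained = np.arange(sc.n_obs)
    return HCPseudoLabels(
        hc_indices=retained, labels=labels[retained], provenance="backend-clustering",
    )
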