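"""Stage II: redundancy-graph hierarchical gene clustering.

A complete gene graph weighted by composite redundancy is reduced to its
maximum spanning tree (MST). Each MST edge carries a relative redundancy
index (RRI) — redundancy normalized by the larger of the pair's minimum
relevance and their complementarity. Sweeping an RRI threshold upward removes
edges in increasing-RRI order and yields a hierarchy of gene clusters, from
which the most persistent ("stable") clusters are selected by the Excess of
Mass rule; components falling below the minimum size at a split are treated
as fall-out and merged back into their parent cluster. Thresholds are capped
at 1: an edge with RRI >= 1 is never cut, so two genes are separated only if
their redundancy is below either their complementarity or their minimum
relevance somewhere along the MST path between them.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Gene retention
# ---------------------------------------------------------------------------

def retain_top_relevant(
    relevance_sc: Optional[np.ndarray],
    relevance_srt: Optional[np.ndarray],
    q: float = 0.8,
    always_keep: Sequence[int] = (),
) -> np.ndarray:
    """Indices of genes in the top ``q`` fraction by relevance in every
    available modality (intersection). ``always_keep`` indices bypass the rule."""
    if not (0 < q <= 1):
        raise ValueError("q must lie in (0, 1]")
    vectors = [v for v in (relevance_sc, relevance_srt) if v is not None]
    if not vectors:
        raise ValueError("at least one relevance vector required")
    n = len(vectors[0])
    m = int(np.ceil(q * n))
    keep = np.ones(n, dtype=bool)
    for v in vectors:
        order = np.argsort(-np.asarray(v), kind="stable")
        mask = np.zeros(n, dtype=bool)
        mask[order[:m]] = True
        keep &= mask
    keep[np.asarray(list(always_keep), dtype=int)] = True
    retained = np.flatnonzero(keep)
    if retained.size == 0:
        raise ValueError("no gene passes the retention rule in all modalities; lower q")
    return retained


# ---------------------------------------------------------------------------
# Maximum spanning tree (Prim)
# ---------------------------------------------------------------------------

def maximum_spanning_tree(
    weights: np.ndarray, gene_ids: Sequence[str]
) -> list[tuple[int, int, float]]:
    """MST maximizing total weight on a complete graph, by Prim's algorithm.

    Deterministic: ties are broken by lexicographic gene-pair order. Returns
    edges as (i, j, weight) with i, j indices into ``gene_ids``.
    """
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    if n < 2:
        raise ValueError("need at least 2 retained genes")
    names = list(gene_ids)
    start = min(range(n), key=lambda i: names[i])
    in_tree = np.zeros(n, dtype=bool)
    in_tree[start] = True
    heap: list[tuple[float, tuple[str, str], int, int]] = []

    def push(u: int) -> None:
        for v in range(n):
            if not in_tree[v]:
                pair = (min(names[u], names[v]), max(names[u], names[v]))
                heapq.heappush(heap, (-W[u, v], pair, u, v))

    push(start)
    edges: list[tuple[int, int, float]] = []
    while len(edges) < n - 1:
        negw, _, u, v = heapq.heappop(heap)
        if in_tree[v]:
            continue
        in_tree[v] = True
        edges.append((u, v, -negw))
        push(v)
    return edges


def edge_rri(red: float, rel_i: float, rel_j: float, comp: float) -> float:
    """Relative redundancy index of an MST edge.

    RRI = Red / max(min(Rel_i, Rel_j), Comp); a zero denominator yields +inf
    (the edge is never cut).
    """
    denom = max(min(rel_i, rel_j), comp)
    if denom == 0:
        return float("inf")
    return red / denom


# ---------------------------------------------------------------------------
# Condensed hierarchy + Excess of Mass
# ---------------------------------------------------------------------------

@dataclass
class ClusterRecord:
    id: int
    parent: Optional[int]
    birth: float
    death: float
    members: np.ndarray                 # gene indices ever belonging to the cluster
    leave_at: np.ndarray                # lambda at which each member leaves
    children: list[int] = field(default_factory=list)

    @property
    def stability(self) -> float:
        return float(np.sum(self.leave_at - self.birth))


@dataclass
class GeneClusterHierarchy:
    """MST, RRI-condensed hierarchy, stability scores, and final assignment."""

    gene_ids: list[str]
    mst_edges: list[tuple[int, int, float]]      # (i, j, redundancy weight)
    rri: np.ndarray                              # per MST edge
    clusters: list[ClusterRecord]
    selected: list[int]
    assignment: np.ndarray                       # cluster label (0..K-1) per gene

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.max()) + 1 if self.assignment.size else 0


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def eom_partition(
    n_genes: int,
    gene_ids: Sequence[str],
    mst_edges: Sequence[tuple[int, int, float]],
    rri: Sequence[float],
    min_size: int = 5,
    max_threshold: float = 1.0,
    target_n_clusters: Optional[int] = None,
) -> GeneClusterHierarchy:
    """Partition the MST into gene clusters via the RRI threshold hierarchy.

    Edges with RRI >= ``max_threshold`` are permanent. The remaining edges are
    removed in increasing-RRI order; each removal either truly splits a cluster
    (both sides >= ``min_size``: children born, parent dies), sheds fall-out
    (one side < ``min_size``: its genes leave, the cluster continues), or ends
    the cluster (both sides small). Cluster stability is the summed RRI span
    each member spends inside the cluster; the Excess-of-Mass rule selects the
    stability-optimal antichain. ``target_n_clusters`` overrides the automatic
    selection with the antichain whose cluster count is closest to the target
    (ties resolved toward higher total stability).
    """
    names = list(gene_ids)
    rri = np.asarray(rri, dtype=float)
    if min_size > n_genes or n_genes == 1 or not mst_edges:
        rec = ClusterRecord(0, None, 0.0, max_threshold,
                            members=np.arange(n_genes),
                            leave_at=np.full(n_genes, max_threshold))
        return GeneClusterHierarchy(names, list(mst_edges), rri, [rec], [0],
                                    np.zeros(n_genes, dtype=int))

    # contract permanent edges into atoms
    uf = _UnionFind(n_genes)
    cuttable: list[tuple[float, tuple[str, str], int, int]] = []
    for (i, j, _w), r in zip(mst_edges, rri):
        if r >= max_threshold:
            uf.union(i, j)
        else:
            pair = (min(names[i], names[j]), max(names[i], names[j]))
            cuttable.append((r, pair, i, j))
    roots = {}
    atom_genes: list[list[int]] = []
    for g in range(n_genes):
        r = uf.find(g)
        if r not in roots:
            roots[r] = len(atom_genes)
            atom_genes.append([])
        atom_genes[roots[r]].append(g)
    n_atoms = len(atom_genes)

    # dendrogram bottom-up: merge atoms in DECREASING rri order
    # node ids: 0..n_atoms-1 atoms, then internal nodes
    cuttable.sort(key=lambda t: (-t[0], t[1]))
    children: dict[int, tuple[int, int]] = {}
    merge_rri: dict[int, float] = {}
    sizes: dict[int, int] = {a: len(atom_genes[a]) for a in range(n_atoms)}
    node_of = _UnionFind(n_genes)
    for (i, j, _w), r in zip(mst_edges, rri):
        if r >= max_threshold:
            node_of.union(i, j)
    current_node = {node_of.find(genes[0]): a for a, genes in enumerate(atom_genes)}
    next_id = n_atoms
    for r, _pair, i, j in cuttable:
        ri, rj = node_of.find(i), node_of.find(j)
        a, b = current_node[ri], current_node[rj]
        if a == b:  # cannot happen on a tree; guard for safety
            continue
        node_of.union(i, j)
        root = node_of.find(i)
        children[next_id] = (a, b)
        merge_rri[next_id] = r
        sizes[next_id] = sizes[a] + sizes[b]
        del current_node[ri], current_node[rj]
        current_node[root] = next_id
        next_id += 1
    assert len(current_node) == 1, "MST must yield a single dendrogram root"
    root_node = next(iter(current_node.values()))

    def leaf_genes(node: int) -> np.ndarray:
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < n_atoms:
                out.extend(atom_genes[v])
            else:
                stack.extend(children[v])
        return np.array(sorted(out), dtype=int)

    # condense: walk top-down creating clusters
    clusters: list[ClusterRecord] = []

    def new_cluster(parent: Optional[int], birth: float) -> int:
        cid = len(clusters)
        clusters.append(ClusterRecord(cid, parent, birth, birth,
                                      members=np.empty(0, int),
                                      leave_at=np.empty(0)))
        if parent is not None:
            clusters[parent].children.append(cid)
        return cid

    stack: list[tuple[int, int]] = [(new_cluster(None, 0.0), root_node)]
    while stack:
        cid, node = stack.pop()
        members: list[int] = []
        leave: list[float] = []
        v = node
        while v >= n_atoms:
            lam = merge_rri[v]
            a, b = children[v]
            big = [c for c in (a, b) if sizes[c] >= min_size]
            if len(big) == 2:
                for g in leaf_genes(v):
                    members.append(g)
                    leave.append(lam)
                clusters[cid].death = lam
                stack.append((new_cluster(cid, lam), a))
                stack.append((new_cluster(cid, lam), b))
                v = -1
                break
            if len(big) == 1:
                small = b if big[0] == a else a
                for g in leaf_genes(small):
                    members.append(g)
                    leave.append(lam)
                v = big[0]
            else:  # both sides small: the cluster ends here
                for g in leaf_genes(v):
                    members.append(g)
                    leave.append(lam)
                clusters[cid].death = lam
                v = -1
                break
        if v != -1:  # reached an atom (or cluster survived to the cap)
            for g in (leaf_genes(v) if v >= 0 else []):
                members.append(g)
                leave.append(max_threshold)
            clusters[cid].death = max_threshold
        clusters[cid].members = np.array(members, dtype=int)
        clusters[cid].leave_at = np.array(leave, dtype=float)

    selected = _select_clusters(clusters, target_n_clusters)
    assignment = _assign(clusters, selected, n_genes, mst_edges, rri)
    return GeneClusterHierarchy(
        gene_ids=names,
        mst_edges=list(mst_edges),
        rri=rri,
        clusters=clusters,
        selected=selected,
        assignment=assignment,
    )


def _select_clusters(
    clusters: list[ClusterRecord], target: Optional[int]
) -> list[int]:
    depth: dict[int, float] = {}
    for rec in clusters:  # records are created parent-before-child
        depth[rec.id] = 0 if rec.parent is None else depth[rec.parent] + 1
    order = sorted(range(len(clusters)), key=lambda c: depth[c], reverse=True)
    if target is None:
        # Excess of Mass: keep a cluster if it is more stable than the sum of
        # its selected descendants. The root's birth threshold (0) is an
        # artifact of where the sweep starts, so a root that ever splits is
        # never selected itself — the standard condensed-tree convention.
        subtree: dict[int, float] = {}
        chosen: dict[int, list[int]] = {}
        for cid in order:
            rec = clusters[cid]
            if not rec.children:
                subtree[cid] = rec.stability
                chosen[cid] = [cid]
                continue
            child_sum = sum(subtree[c] for c in rec.children)
            if rec.stability >= child_sum and rec.parent is not None:
                subtree[cid] = rec.stability
                chosen[cid] = [cid]
            else:
                subtree[cid] = max(child_sum, rec.stability)
                chosen[cid] = [c for ch in rec.children for c in chosen[ch]]
        return sorted(chosen[_root_id(clusters)])

    # target-count mode: grow an antichain from the root, expanding the
    # cluster with the largest stability gain first
    antichain = {_root_id(clusters)}
    best = (abs(len(antichain) - target), -_total_stability(clusters, antichain), set(antichain))
    while True:
        expandable = [c for c in antichain if clusters[c].children]
        if not expandable:
            break
        gains = {
            c: sum(clusters[ch].stability for ch in clusters[c].children) - clusters[c].stability
            for c in expandable
        }
        pick = max(expandable, key=lambda c: gains[c])
        antichain.remove(pick)
        antichain.update(clusters[pick].children)
        cand = (abs(len(antichain) - target), -_total_stability(clusters, antichain), set(antichain))
        if cand[:2] < best[:2]:
            best = cand
        if len(antichain) >= target and abs(len(antichain) - target) >= best[0]:
            break
    return sorted(best[2])


def _root_id(clusters: list[ClusterRecord]) -> int:
    return next(c.id for c in clusters if c.parent is None)


def _total_stability(clusters: list[ClusterRecord], ids: set[int]) -> float:
    return sum(clusters[c].stability for c in ids)


def _assign(
    clusters: list[ClusterRecord],
    selected: list[int],
    n_genes: int,
    mst_edges: Sequence[tuple[int, int, float]],
    rri: np.ndarray,
) -> np.ndarray:
    """Final gene -> cluster map.

    Selected clusters form an antichain with disjoint member sets. Genes that
    fell out above the antichain (noise shed by an unselected ancestor) are
    merged back along the MST: labels are propagated over MST edges in
    decreasing-RRI order, attaching each such gene to the selected cluster it
    is most redundant with.
    """
    assignment = np.full(n_genes, -1, dtype=int)
    for rank, cid in enumerate(sorted(selected)):
        assignment[clusters[cid].members] = rank
    if np.any(assignment < 0):
        order = sorted(
            range(len(mst_edges)),
            key=lambda e: (-rri[e] if np.isfinite(rri[e]) else -np.inf, e),
        )
        # iterate until fixed point: a tree needs at most n passes, usually 1-2
        changed = True
        while changed and np.any(assignment < 0):
            changed = False
            for e in order:
                i, j, _w = mst_edges[e]
                if assignment[i] >= 0 and assignment[j] < 0:
                    assignment[j] = assignment[i]
                    changed = True
                elif assignment[j] >= 0 and assignment[i] < 0:
                    assignment[i] = assignment[j]
                    changed = True
    # relabel to consecutive ids ordered by first occurrence, for stability
    uniq = pd.unique(assignment)
    remap = {old: new for new, old in enumerate(uniq)}
    return np.array([remap[a] for a in assignment], dtype=int)


def cluster_table(
    hierarchy: GeneClusterHierarchy, relevance: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-level assignment table and per-cluster summaries (size, max
    composite relevance — the downstream ranking key)."""
    genes = pd.DataFrame({
        "gene": hierarchy.gene_ids,
        "cluster": hierarchy.assignment,
        "relevance": np.asarray(relevance, dtype=float),
    })
    summary = (
        genes.groupby("cluster")
        .agg(size=("gene", "size"), max_rel_com=("relevance", "max"))
        .reset_index()
        .sort_values("max_rel_com", ascending=False, ignore_index=True)
    )
    return genes, summary
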