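"""Paired spatial + single-cell synthetic data with planted co-expression modules.

The generator emulates the structure the method assumes in real tissue: a spot
lattice (square or Visium-like hexagonal) partitioned into spatially contiguous
domains, a cell population partitioned into types, and gene modules whose mean
expression is jointly elevated in a module-specific set of domains (spatial
modality) and cell types (single-cell modality). Counts are negative-binomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ExpressionDataset, PairedDatasets

NOISE = -1  # module id for genes without planted structure


@dataclass
class SyntheticConfig:
    """Parameters of the paired generator.

    ``module_effect`` is the fold change of a module gene's mean between its
    active domains/types and everywhere else (must exceed 1). ``dispersion``
    is the negative-binomial shape theta in the (mean, theta)
    parameterization, var = mu + mu^2/theta: larger theta = less noise.
    ``n_confounded_pairs`` forces that many module pairs to share the same
    active domains while keeping disjoint active cell types, so they are
    indistinguishable in the spatial modality alone.

    Per-gene baseline means are log-normal (median ``baseline_mean``, log-sd
    ``baseline_sigma``), mirroring the orders-of-magnitude spread of real
    transcriptomes; every module reuses the same baseline multiset so the
    total active expression mass stays balanced across domains and cell types.
    """

    grid_shape: tuple[int, int] = (16, 16)
    lattice: str = "hex"
    n_domains: int = 4
    n_cell_types: int = 4
    n_cells: int = 500
    n_genes: int = 200
    n_modules: int = 4
    module_effect: float = 8.0
    dispersion: float = 10.0
    noise_gene_fraction: float = 0.2
    baseline_mean: float = 1.0
    baseline_sigma: float = 0.75
    n_confounded_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if self.n_domains > rows * cols:
            raise ValueError("more domains than lattice sites")
        if self.module_effect < 1:
            raise ValueError("module_effect must be >= 1 (1 = null, no planted signal)")
        if self.lattice not in ("square", "hex"):
            raise ValueError(f"unknown lattice: {self.lattice}")
        n_module_genes = round(self.n_genes * (1 - self.noise_gene_fraction))
        if self.n_modules * 5 > n_module_genes:
            raise ValueError("too many modules for the available genes (min module size 5)")
        if 2 * self.n_confounded_pairs > self.n_modules:
            raise ValueError("not enough modules for the requested confounded pairs")
        if self.n_confounded_pairs and self.n_cell_types < 2 * self.n_confounded_pairs:
            raise ValueError("confounded pairs need disjoint cell types")


@dataclass
class SyntheticTruth:
    """Planted ground truth: gene module map, spot domains, cell types."""

    module_of_gene: dict[str, int]
    domain_of_spot: np.ndarray
    type_of_cell: np.ndarray
    active_map: dict[int, tuple[frozenset, frozenset]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Lattice
# ---------------------------------------------------------------------------

def lattice_coordinates(grid_shape: tuple[int, int]) -> np.ndarray:
    rows, cols = grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def hex_neighbors(grid_shape: tuple[int, int], lattice: str = "hex") -> list[list[int]]:
    """Adjacency lists on an odd-row-offset hex lattice (6 interior neighbors)
    or a square lattice (4)."""
    rows, cols = grid_shape

    def idx(r: int, c: int) -> int:
        return r * cols + c

    adj: list[list[int]] = [[] for _ in range(rows * cols)]
    for r in range(rows):
        for c in range(cols):
            if lattice == "square":
                offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
            else:
                # odd-row offset coordinates
                if r % 2 == 0:
                    offsets = [(0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0)]
                else:
                    offsets = [(0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1)]
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    adj[idx(r, c)].append(idx(rr, cc))
    return adj


def _multi_source_bfs(adjacency: list[list[int]], sources: list[int]) -> np.ndarray:
    dist = np.full(len(adjacency), -1, dtype=int)
    queue = list(sources)
    for s in sources:
        dist[s] = 0
    head = 0
    while head < len(queue):
        v = queue[head]
        head += 1
        for u in adjacency[v]:
            if dist[u] < 0:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def grow_domains(
    adjacency: list[list[int]], n_domains: int, rng: np.random.Generator
) -> np.ndarray:
    """Partition lattice sites into contiguous domains by seeded region growing.

    Growth is balanced and compact: each step extends the currently smallest
    domain that still has room to grow, preferring the frontier site with the
    most same-domain neighbors. This yields contiguous domains of comparable
    size with smooth boundaries, as tissue domains typically are.
    """
    n = len(adjacency)
    labels = np.full(n, -1, dtype=int)
    # farthest-point seed placement: well-separated seeds avoid strangling any
    # domain against another's front
    seeds = [int(rng.integers(n))]
    while len(seeds) < n_domains:
        dist = _multi_source_bfs(adjacency, seeds)
        best = np.flatnonzero(dist == dist.max())
        seeds.append(int(best[rng.integers(len(best))]))
    frontiers: list[list[int]] = [[] for _ in range(n_domains)]
    sizes = np.ones(n_domains, dtype=int)
    for k, s in enumerate(seeds):
        labels[s] = k
        frontiers[k] = [v for v in adjacency[s] if labels[v] == -1]
    remaining = n - n_domains
    while remaining > 0:
        progressed = False
        for k in np.argsort(sizes, kind="stable"):
            frontier = [v for v in frontiers[k] if labels[v] == -1]
            frontiers[k] = frontier
            if not frontier:
                continue
            support = np.array([
                sum(labels[u] == k for u in adjacency[v]) for v in frontier
            ])
            best = np.flatnonzero(support == support.max())
            v = frontier[int(best[rng.integers(len(best))])]
            labels[v] = k
            sizes[k] += 1
            frontiers[k] = [u for u in frontier if u != v] + [
                u for u in adjacency[v] if labels[u] == -1
            ]
            remaining -= 1
            progressed = True
            break
        if not progressed:  # enclosed leftovers: attach to a labeled neighbor
            for v in np.flatnonzero(labels == -1):
                labels[v] = next((labels[u] for u in adjacency[v] if labels[u] != -1), 0)
            remaining = 0
    return labels


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _nb_counts(mean: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def generate_paired(config: SyntheticConfig) -> tuple[PairedDatasets, SyntheticTruth]:
    """Generate a paired spatial + single-cell fixture and its ground truth.

    Module m's genes have mean ``baseline * module_effect`` in the module's
    active domains (spots) and active cell types (cells), baseline elsewhere.
    Noise genes are flat everywhere. All randomness derives from the seed.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid_shape
    n_spots = rows * cols
    adjacency = hex_neighbors(config.grid_shape, config.lattice)
    domain_of_spot = grow_domains(adjacency, config.n_domains, rng)
    type_of_cell = rng.integers(config.n_cell_types, size=config.n_cells)

    n_noise = round(config.n_genes * config.noise_gene_fraction)
    n_module_genes = config.n_genes - n_noise
    sizes = np.full(config.n_modules, n_module_genes // config.n_modules)
    sizes[: n_module_genes % config.n_modules] += 1

    # Active sets: modules are grouped by domain activity (confounded pairs
    # share one group; the rest are singleton groups), and the domains are
    # split into equal contiguous blocks, one per group. Equal blocks keep the
    # total active gene mass balanced across domains, so library size carries
    # no domain information. Cell types are assigned one per module, which
    # keeps per-type mass balanced and makes confounded pairs separable only
    # in the single-cell modality.
    groups: list[list[int]] = [
        [2 * p, 2 * p + 1] for p in range(config.n_confounded_pairs)
    ] + [[m] for m in range(2 * config.n_confounded_pairs, config.n_modules)]
    blocks = np.array_split(np.arange(config.n_domains), len(groups))
    active_map: dict[int, tuple[frozenset, frozenset]] = {}
    for grp, block in zip(groups, blocks):
        doms = frozenset(int(d) for d in block)
        for m in grp:
            active_map[m] = (doms, frozenset({m % config.n_cell_types}))

    gene_ids, module_of_gene = [], {}
    gene_modules = []
    g = 0
    for m in range(config.n_modules):
        for _ in range(sizes[m]):
            name = f"G{g:04d}_M{m}"
            gene_ids.append(name)
            module_of_gene[name] = m
            gene_modules.append(m)
            g += 1
    for _ in range(n_noise):
        name = f"G{g:04d}_noise"
        gene_ids.append(name)
        module_of_gene[name] = NOISE
        gene_modules.append(NOISE)
        g += 1
    gene_modules = np.array(gene_modules)

    # per-gene baselines: one shared log-normal pool across modules keeps the
    # active mass balanced; noise genes draw independently
    pool = config.baseline_mean * rng.lognormal(0.0, config.baseline_sigma,
                                                size=int(sizes.max()) if len(sizes) else 0)
    baselines = np.empty(config.n_genes)
    for m in range(config.n_modules):
        baselines[gene_modules == m] = pool[: sizes[m]]
    baselines[gene_modules == NOISE] = config.baseline_mean * rng.lognormal(
        0.0, config.baseline_sigma, size=n_noise)
    eff = config.module_effect

    def mean_matrix(group_of_obs: np.ndarray, which: int) -> np.ndarray:
        mu = np.tile(baselines, (len(group_of_obs), 1))
        for m, (doms, types) in active_map.items():
            active_groups = doms if which == 0 else types
            obs_mask = np.isin(group_of_obs, list(active_groups))
            gene_mask = gene_modules == m
            mu[np.ix_(obs_mask, gene_mask)] *= eff
        return mu

    srt_counts = _nb_counts(mean_matrix(domain_of_spot, 0), config.dispersion, rng)
    sc_counts = _nb_counts(mean_matrix(type_of_cell, 1), config.dispersion, rng)

    srt = ExpressionDataset(
        counts=srt_counts,
        gene_ids=list(gene_ids),
        obs_ids=[f"spot{i:04d}" for i in range(n_spots)],
        modality="SRT",
        coordinates=lattice_coordinates(config.grid_shape),
        labels=domain_of_spot.astype(str),
    )
    sc = ExpressionDataset(
        counts=sc_counts,
        gene_ids=list(gene_ids),
        obs_ids=[f"cell{i:04d}" for i in range(config.n_cells)],
        modality="SC",
        labels=type_of_cell.astype(str),
    )
    truth = SyntheticTruth(
        module_of_gene=module_of_gene,
        domain_of_spot=domain_of_spot,
        type_of_cell=type_of_cell,
        active_map=active_map,
    )
    return PairedDatasets(srt=srt, sc=sc, shared_genes=list(gene_ids)), truth
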