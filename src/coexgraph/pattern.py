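"""Designated-pattern gene discovery via a simulated pseudo-gene.

A target spatial expression pattern is declared as expression levels per
tissue region on a five-step scale anchored at percentiles of the per-gene
mean expression distribution: "very-high" = 95th percentile, "high" = 85th,
"moderate-high" = 75th, "moderate" = 65th, "low" = 35th. A pseudo-gene
realizing the pattern (plus proportional Gaussian noise) is appended to the
spatial dataset and co-clustered with the real genes in spatial-only mode;
the members of its cluster, ranked by redundancy with it, are the genes
matching the designated pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, PairedDatasets
from .pipeline import ClusterRunResult, RunConfig, run_cluster

PSEUDO_GENE_PREFIX = "__pseudo__"

LEVEL_PERCENTILES: dict[str, float] = {
    "very-high": 95.0,
    "high": 85.0,
    "moderate-high": 75.0,
    "moderate": 65.0,
    "low": 35.0,
}


@dataclass
class PatternSpec:
    """Region -> level mapping; unlisted regions default to ``default_level``.

    Regions are the categories of a per-spot annotation vector; the declared
    regions must be disjoint by construction (one label per spot).
    """

    region_levels: Mapping[str, str] = field(default_factory=dict)
    default_level: str = "low"

    def __post_init__(self) -> None:
        for lv in list(self.region_levels.values()) + [self.default_level]:
            if lv not in LEVEL_PERCENTILES:
                raise ValueError(f"unknown level {lv!r}; choose from {sorted(LEVEL_PERCENTILES)}")


def level_values(srt: ExpressionDataset) -> dict[str, float]:
    """Map each level name to an expression value: the level's percentile of
    the distribution of per-gene mean normalized expression across spots
    (linear-interpolation percentile)."""
    if srt.normalized is None:
        raise ValueError("dataset must be preprocessed first")
    gene_means = srt.normalized.mean(axis=0)
    return {
        name: float(np.percentile(gene_means, pct))
        for name, pct in LEVEL_PERCENTILES.items()
    }


def simulate_pseudo_gene(
    spec: PatternSpec,
    srt: ExpressionDataset,
    region_of_spot: Optional[np.ndarray] = None,
    noise_sd_fraction: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Per-spot expression vector realizing the designated pattern.

    Each spot receives its region's level value plus seeded Gaussian noise
    with standard deviation ``noise_sd_fraction`` times that value.
    """
    regions = np.asarray(region_of_spot if region_of_spot is not None else srt.labels)
    if regions is None or regions.shape[0] != srt.n_obs:
        raise ValueError("need one region label per spot")
    unknown = set(spec.region_levels) - set(str(r) for r in regions)
    if unknown:
        raise ValueError(f"pattern references unknown regions: {sorted(unknown)}")
    values = level_values(srt)
    base = np.array([
        values[spec.region_levels.get(str(r), spec.default_level)] for r in regions
    ])
    rng = np.random.default_rng(seed)
    noisy = base + rng.standard_normal(srt.n_obs) * (noise_sd_fraction * base)
    return np.maximum(noisy, 0.0)


def append_pseudo_gene(
    srt: ExpressionDataset, vector: np.ndarray, name: str = f"{PSEUDO_GENE_PREFIX}pattern"
) -> ExpressionDataset:
    """Dataset copy with the pseudo-gene appended as an extra gene.

    The count column is a rounded inverse-log placeholder (counts are not used
    by the metric stage beyond library-size bookkeeping).
    """
    counts = np.rint(np.expm1(vector)).astype(srt.counts.dtype)[:, None]
    return replace(
        srt,
        counts=np.hstack([srt.counts, counts]),
        gene_ids=list(srt.gene_ids) + [name],
        normalized=np.hstack([srt.normalized, np.asarray(vector, float)[:, None]]),
    )


def find_pattern_genes(
    spec: PatternSpec,
    srt: ExpressionDataset,
    region_of_spot: Optional[np.ndarray] = None,
    config: Optional[RunConfig] = None,
    noise_sd_fraction: float = 0.1,
    seed: int = 0,
    spot_labels: Optional[np.ndarray] = None,
) -> tuple[pd.DataFrame, ClusterRunResult]:
    """Genes co-clustering with the designated-pattern pseudo-gene.

    Runs the clustering pipeline in spatial-only mode (w = 0) with the
    pseudo-gene appended and exempted from relevance-based retention; returns
    the other members of its cluster ranked by redundancy with it (descending),
    plus the full run result. An empty frame (with a warning) means the
    pseudo-gene landed in a singleton group — no gene matches the pattern.
    """
    config = config or RunConfig(mode="srt_only", seed=seed)
    if config.mode != "srt_only":
        config = replace(config, mode="srt_only")
    vector = simulate_pseudo_gene(spec, srt, region_of_spot, noise_sd_fraction, seed)
    name = f"{PSEUDO_GENE_PREFIX}pattern"
    augmented = append_pseudo_gene(srt, vector, name)
    paired = PairedDatasets(srt=augmented, sc=augmented, shared_genes=list(augmented.gene_ids))
    result = run_cluster(
        paired, config,
        spot_labels=spot_labels if spot_labels is not None else region_of_spot,
        always_keep_genes=[name],
    )
    gene_ids = result.hierarchy.gene_ids
    if name not in gene_ids:
        raise AssertionError("pseudo-gene must survive retention")
    p = gene_ids.index(name)
    cluster = result.hierarchy.assignment[p]
    members = [
        i for i in np.flatnonzero(result.hierarchy.assignment == cluster) if i != p
    ]
    if not members:
        warnings.warn("pseudo-gene fell into a singleton group; no matching genes")
        return pd.DataFrame(columns=["gene", "redundancy"]), result
    table = pd.DataFrame({
        "gene": [gene_ids[i] for i in members],
        "redundancy": [result.metrics.redundancy[p, i] for i in members],
    }).sort_values(["redundancy", "gene"], ascending=[False, True], ignore_index=True)
    return table, result
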