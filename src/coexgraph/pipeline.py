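"""End-to-end orchestration: pseudo-labeling -> info metrics -> gene clustering,
feature-gene selection, and interaction networks, with a reproducible manifest.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .clustering import (
    GeneClusterHierarchy,
    cluster_table,
    edge_rri,
    eom_partition,
    maximum_spanning_tree,
    retain_top_relevant,
)
from .datasets import ExpressionDataset, PairedDatasets, preprocess
from .infometrics import (
    InfoMetrics,
    compute_modality_metrics,
    fuse_composite,
    hc_expression,
    relevance_vector,
)
from .interactions import PartialCorrelationNetwork, build_network
from .pseudolabel import HCPseudoLabels, hc_spots, pseudo_label_cells


@dataclass
class RunConfig:
    """Parameters of an end-to-end run.

    ``mode`` selects the modality weighting: "integrated" uses ``w`` in (0,1),
    "srt_only" forces w=0 (spatial metrics only) and "sc_only" forces w=1.
    """

    mode: str = "integrated"
    w: float = 0.5
    estimator: str = "binned"
    k: int = 3
    n_bins: int = 8
    retention_q: float = 0.8
    min_cluster_size: int = 5
    max_rri_threshold: float = 1.0
    target_n_clusters: Optional[int] = None
    alpha: float = 0.1
    epsilon: float = 1e-6
    n_domains: Optional[int] = None
    n_cell_types: Optional[int] = None
    hc_fraction: float = 0.6
    feature_percentile: float = 80.0
    seed: int = 0

    def effective_w(self) -> float:
        if self.mode == "integrated":
            if not (0 < self.w < 1):
                raise ValueError("integrated mode requires w strictly inside (0, 1)")
            return self.w
        if self.mode == "srt_only":
            return 0.0
        if self.mode == "sc_only":
            return 1.0
        raise ValueError(f"unknown mode: {self.mode}")


@dataclass
class ClusterRunResult:
    hierarchy: GeneClusterHierarchy
    metrics: InfoMetrics
    retained: np.ndarray                   # indices into shared_genes
    shared_genes: list[str]
    hc_srt: Optional[HCPseudoLabels]
    hc_sc: Optional[HCPseudoLabels]
    gene_table: pd.DataFrame
    cluster_summary: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    @property
    def assignment(self) -> dict[str, int]:
        return dict(zip(self.hierarchy.gene_ids, self.hierarchy.assignment))


def _ensure_preprocessed(ds: Optional[ExpressionDataset]) -> Optional[ExpressionDataset]:
    if ds is None or ds.normalized is not None:
        return ds
    return preprocess(ds)


def run_cluster(
    paired: PairedDatasets,
    config: RunConfig = RunConfig(),
    spot_labels: Optional[np.ndarray] = None,
    cell_labels: Optional[np.ndarray] = None,
    spatial_backend: Optional[Callable] = None,
    cell_backend: Optional[Callable] = None,
    always_keep_genes: Sequence[str] = (),
) -> ClusterRunResult:
    """Full clustering pipeline on a paired (or single-modality) input.

    Stages: HC pseudo-labeling of spots (and cells), per-modality relevance,
    relevance-based gene retention, pairwise redundancy/complementarity on the
    retained genes, composite fusion, redundancy-graph MST, RRI hierarchy with
    Excess-of-Mass selection. Deterministic given ``config.seed``.
    """
    t0 = time.time()
    w = config.effective_w()
    srt = _ensure_preprocessed(paired.srt) if w < 1 else None
    sc = _ensure_preprocessed(paired.sc) if w > 0 else None
    genes = None
    for ds in (srt, sc):
        if ds is not None:
            genes = ds.gene_ids if genes is None else genes
            if ds.gene_ids != genes:
                raise ValueError("modalities must be aligned to the same gene order")
    n_genes = len(genes)

    hc_srt = hc_sc = None
    rel_srt = rel_sc = None
    if srt is not None:
        hc_srt = hc_spots(srt, labels=spot_labels, backend=spatial_backend,
                          n_domains=config.n_domains, fraction=config.hc_fraction)
        X, lab = hc_expression(srt, hc_srt)
        rel_srt = relevance_vector(X, lab, config.estimator, config.k,
                                   config.n_bins, config.seed)
    if sc is not None:
        if cell_labels is not None:
            hc_sc = HCPseudoLabels(np.arange(sc.n_obs), np.asarray(cell_labels), "user")
        else:
            hc_sc = pseudo_label_cells(sc, backend=cell_backend, n_types=config.n_cell_types)
        X, lab = hc_expression(sc, hc_sc)
        rel_sc = relevance_vector(X, lab, config.estimator, config.k,
                                  config.n_bins, config.seed)

    keep_idx = [genes.index(g) for g in always_keep_genes]
    retained = retain_top_relevant(rel_sc, rel_srt, q=config.retention_q,
                                   always_keep=keep_idx)

    metrics_srt = metrics_sc = None
    if srt is not None:
        metrics_srt = compute_modality_metrics(
            srt, hc_srt, gene_subset=retained, estimator=config.estimator,
            k=config.k, n_bins=config.n_bins, seed=config.seed)
    if sc is not None:
        metrics_sc = compute_modality_metrics(
            sc, hc_sc, gene_subset=retained, estimator=config.estimator,
            k=config.k, n_bins=config.n_bins, seed=config.seed)
    metrics = fuse_composite(metrics_sc, metrics_srt, w)

    mst = maximum_spanning_tree(metrics.redundancy, metrics.gene_ids)
    rri = np.array([
        edge_rri(metrics.redundancy[i, j], metrics.relevance[i],
                 metrics.relevance[j], metrics.complementarity[i, j])
        for i, j, _w in mst
    ])
    hierarchy = eom_partition(
        len(metrics.gene_ids), metrics.gene_ids, mst, rri,
        min_size=config.min_cluster_size,
        max_threshold=config.max_rri_threshold,
        target_n_clusters=config.target_n_clusters,
    )
    gene_table, summary = cluster_table(hierarchy, metrics.relevance)
    manifest = {
        "config": asdict(config),
        "package_version": _pkg_version,
        "n_shared_genes": n_genes,
        "n_retained_genes": int(retained.size),
        "n_clusters": hierarchy.n_clusters,
        "elapsed_s": round(time.time() - t0, 3),
    }
    return ClusterRunResult(
        hierarchy=hierarchy, metrics=metrics, retained=retained,
        shared_genes=list(genes), hc_srt=hc_srt, hc_sc=hc_sc,
        gene_table=gene_table, cluster_summary=summary, manifest=manifest,
    )


def run_select_features(
    result: ClusterRunResult, percentile: Optional[float] = None
) -> list[str]:
    """Representative genes: per cluster, those whose composite relevance is at
    or above the cluster's 80th relevance percentile (linear interpolation);
    output is the union over clusters, so every cluster contributes."""
    pct = 80.0 if percentile is None else percentile
    table = result.gene_table
    out: list[str] = []
    for _, grp in table.groupby("cluster"):
        cut = np.percentile(grp["relevance"].to_numpy(), pct)
        out.extend(grp.loc[grp["relevance"] >= cut, "gene"].tolist())
    return sorted(out)


def run_interactions(
    paired: PairedDatasets,
    config: RunConfig = RunConfig(),
    genes: Optional[Sequence[str]] = None,
    spot_labels: Optional[np.ndarray] = None,
    cell_labels: Optional[np.ndarray] = None,
) -> PartialCorrelationNetwork:
    """Partial-correlation network for one condition.

    The composite redundancy table over ``genes`` (default: all shared genes)
    is sign-adjusted by the combined Pearson correlation and pushed through a
    graphical lasso at ``config.alpha``.
    """
    w = config.effective_w()
    srt = _ensure_preprocessed(paired.srt)
    sc = _ensure_preprocessed(paired.sc)
    genes = list(genes) if genes is not None else list(srt.gene_ids)
    gidx = [srt.gene_ids.index(g) for g in genes]

    hc_srt = hc_spots(srt, labels=spot_labels, n_domains=config.n_domains,
                      fraction=config.hc_fraction)
    if cell_labels is not None:
        hc_sc = HCPseudoLabels(np.arange(sc.n_obs), np.asarray(cell_labels), "user")
    else:
        hc_sc = pseudo_label_cells(sc, n_types=config.n_cell_types)

    m_srt = compute_modality_metrics(
        srt, hc_srt, gene_subset=gidx, estimator=config.estimator,
        k=config.k, n_bins=config.n_bins, seed=config.seed)
    m_sc = compute_modality_metrics(
        sc, hc_sc, gene_subset=gidx, estimator=config.estimator,
        k=config.k, n_bins=config.n_bins, seed=config.seed)
    metrics = fuse_composite(m_sc, m_srt, w)

    X_srt, _ = hc_expression(srt, hc_srt)
    X_sc, _ = hc_expression(sc, hc_sc)
    return build_network(
        genes=genes,
        redundancy=metrics.redundancy,
        x_sc=X_sc[:, gidx],
        x_srt=X_srt[:, gidx],
        w=w,
        alpha=config.alpha,
        epsilon=config.epsilon,
    )
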