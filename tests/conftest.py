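import numpy as np
import pytest

import coexgraph as cg


@pytest.fixture(scope="session")
def small_paired():
    """Small paired fixture with 4 planted modules, strong effect."""
    cfg = cg.SyntheticConfig(grid_shape=(12, 12), n_cells=300, n_genes=80,
                             n_modules=4, module_effect=8.0, seed=3)
    paired, truth = cg.generate_paired(cfg)
    srt = cg.preprocess(paired.srt)
    sc = cg.preprocess(paired.sc, min_genes_per_cell=20)
    aligned = cg.align_genes(srt, sc)
    return aligned, truth


@pytest.fixture(scope="session")
def default_paired():
    """The standard study fixture: 4 modules x ~40 genes, effect 8."""
    cfg = cg.SyntheticConfig(seed=11)
    paired, truth = cg.generate_paired(cfg)
    srt = cg.preprocess(paired.srt)
    sc = cg.preprocess(paired.sc, min_genes_per_cell=50)
    aligned = cg.align_genes(srt, sc)
    return aligned, truth


def module_labels(truth, gene_ids):
    return np.array([truth.module_of_gene[g] for g in gene_ids])
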