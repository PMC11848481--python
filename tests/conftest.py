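import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from dfatmap import (
    CountMatrix,
    MethSimConfig,
    ScSimConfig,
    simulate_methylomes,
    simulate_sc_dataset,
)


@pytest.fixture(scope="session")
def small_sc_config():
    return ScSimConfig(
        n_genes=300,
        n_cells_per_cluster=(60, 60),
        n_marker_genes_per_cluster=15,
        marker_fold_change=4.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sc(small_sc_config):
    return simulate_sc_dataset(small_sc_config)


@pytest.fixture(scope="session")
def small_methylomes():
    cfg = MethSimConfig(n_genes=60, cpg_spacing=50, seed=5)
    return simulate_methylomes(cfg)


def toy_count_matrix(counts, genes=None, cells=None, mito=None):
    """Dense list-of-lists (genes x cells) -> CountMatrix."""
    counts = np.asarray(counts)
    n_g, n_c = counts.shape
    genes = genes or [f"g{i}" for i in range(n_g)]
    cells = cells or [f"c{j}" for j in range(n_c)]
    flags = None
    if mito is not None:
        flags = pd.DataFrame(
            {"mito": np.asarray(mito, dtype=bool)}, index=pd.Index(genes)
        )
    return CountMatrix(
        genes=pd.Index(genes),
        cells=pd.Index(cells),
        counts=sp.csr_matrix(counts),
        gene_flags=flags,
    )


@pytest.fixture
def make_counts():
    return toy_count_matrix
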