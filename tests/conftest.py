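import numpy as np
import pytest
import scipy.sparse as sp

import hypoxclass as hx


@pytest.fixture(scope="session")
def sim_small():
    """Small synthetic cohort: 600 cells, 800 genes, 7 sets of 30."""
    return hx.simulate(hx.SimParams(n_cells=600, n_genes=800, set_size=30, seed=7))


@pytest.fixture(scope="session")
def norm_small(sim_small):
    cm, truth, gsc, ann = sim_small
    filtered, _ = hx.qc_filter(cm, ann)
    return hx.log_normalize(filtered)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_norm(matrix, gene_ids=None, cell_ids=None):
    """NormalizedMatrix straight from a dense array of values."""
    matrix = np.asarray(matrix, dtype=float)
    n_c, n_g = matrix.shape
    return hx.NormalizedMatrix(
        cell_ids or [f"c{i}" for i in range(n_c)],
        gene_ids or [f"g{j}" for j in range(n_g)],
        sp.csr_matrix(matrix),
    )
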