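import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from crosscell import CountMatrix


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """3 genes x 4 cells with hand-readable counts."""
    dense = np.array([
        [5, 0, 2, 0],
        [0, 3, 0, 0],
        [1, 0, 2, 0],
    ])
    genes = pd.DataFrame({"gene_id": ["gA", "gB", "gC"],
                          "is_mito": [False, True, False]})
    cells = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(4)],
        "species": ["mouse", "mouse", "opossum", "opossum"],
        "batch": ["batch1"] * 4,
        "tissue": ["brain"] * 4,
        "donor": ["d1", "d2", "d1", "d2"],
    })
    return CountMatrix(sp.csc_matrix(dense), genes, cells)


@pytest.fixture
def small_sim():
    """Small simulated 2-species dataset with truth, shared across tests."""
    from crosscell import simulate_multispecies
    return simulate_multispecies(n_cells_per_species=120, n_genes=50,
                                 n_cell_types=2, seed=7)
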