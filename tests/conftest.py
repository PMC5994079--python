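import numpy as np
import pytest
from scipy import sparse

from drimpute import CountMatrix, SyntheticParams, generate_dataset


@pytest.fixture
def small_counts() -> CountMatrix:
    """4 genes × 3 cells with a mix of zeros and positives."""
    values = np.array(
        [
            [5, 0, 2],
            [0, 3, 1],
            [4, 4, 0],
            [1, 2, 3],
        ]
    )
    return CountMatrix(
        sparse.csr_matrix(values),
        ("gA", "gB", "gC", "gD"),
        ("c1", "c2", "c3"),
    )


@pytest.fixture(scope="session")
def separable_dataset():
    """Small 3-population dataset with clear markers, shared across tests."""
    return generate_dataset(
        SyntheticParams(n_genes=400, n_cells=90, n_clusters=3, seed=7)
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The standard simulation: 2000 genes × 300 cells, 3 clusters, seed 1."""
    return generate_dataset(SyntheticParams(seed=1))
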