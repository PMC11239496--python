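import numpy as np
import pytest
import scipy.sparse as sp

from fatechain.datatypes import NeighborGraph, TransitionMatrix
from fatechain.synthetic import simulate_branching_manifold


@pytest.fixture(scope="session")
def manifold():
    """Small two-branch manifold shared across kernel tests."""
    return simulate_branching_manifold(n_cells=300, n_genes=100, n_branches=2, seed=1)


@pytest.fixture
def line_graph():
    """5 cells on a path, unit edge weights."""
    A = sp.lil_matrix((5, 5))
    for i in range(4):
        A[i, i + 1] = 1.0
        A[i + 1, i] = 1.0
    return NeighborGraph(sp.csr_matrix(A))


@pytest.fixture
def tiny_chain():
    return TransitionMatrix(np.array([[0.5, 0.5], [0.25, 0.75]]))
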