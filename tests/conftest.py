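import numpy as np
import pytest

from connmotif.graph_model import CHEMICAL_ELECTRICAL, MONO, ConnectomeGraph


@pytest.fixture
def bridge_graph() -> ConnectomeGraph:
    """Two directed 3-cycles {0,1,2} and {3,4,5} joined by the edge 2->3."""
    g = ConnectomeGraph(6)
    for (u, v) in [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3), (2, 3)]:
        g.add_edge(u, v)
    return g


@pytest.fixture
def celegans_palette():
    return CHEMICAL_ELECTRICAL


def random_colored_matrix(rng: np.random.Generator, k: int, num_colors: int,
                          self_loops: bool = False) -> np.ndarray:
    mat = rng.integers(0, num_colors + 1, size=(k, k))
    if not self_loops:
        np.fill_diagonal(mat, 0)
    return mat.astype(np.int64)
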