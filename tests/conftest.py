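import logging

import networkx as nx
import numpy as np
import pytest

from codistmod.incidence import IncidenceMatrix, to_bipartite_graph


@pytest.fixture(autouse=True)
def _quiet_logs():
    logging.disable(logging.WARNING)
    yield
    logging.disable(logging.NOTSET)


@pytest.fixture
def two_block_matrix():
    """Two disjoint 2 species x 2 site all-ones blocks (L = 8)."""
    cells = np.zeros((4, 4), dtype=int)
    cells[:2, :2] = 1
    cells[2:, 2:] = 1
    return IncidenceMatrix([f"s{i}" for i in range(4)],
                           [f"r{i}" for i in range(4)], cells)


@pytest.fixture
def two_block_graph(two_block_matrix):
    return to_bipartite_graph(two_block_matrix)


@pytest.fixture
def two_block_partition(two_block_graph):
    from codistmod.modularity import Partition
    block0 = {"sp:s0", "sp:s1", "st:r0", "st:r1"}
    return Partition({v: (0 if v in block0 else 1)
                      for v in two_block_graph.nodes()})


def random_connected_graph(rng, n_min=4, n_max=10, p=0.4):
    """Random graph with at least one edge (for oracle comparisons)."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        if g.number_of_edges() > 0:
            return g
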