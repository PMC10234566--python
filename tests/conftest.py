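import networkx as nx
import numpy as np
import pytest

from rrtd import TaskGraph
from rrtd.enumeration import enumerate_connected_graphs


@pytest.fixture(scope="session")
def eight_node_graphs():
    """The full isomorph-free census of connected eight-node graphs."""
    return list(enumerate_connected_graphs(8))


@pytest.fixture
def p3():
    return TaskGraph("abc", [(0, 1), (1, 2)])


@pytest.fixture
def k3():
    return TaskGraph("abc", [(0, 1), (1, 2), (0, 2)])


def random_connected_graph(n: int, rng: np.random.Generator, p: float = 0.35) -> TaskGraph:
    """A connected Erdos-Renyi draw (resampled until connected)."""
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return TaskGraph.from_networkx(g)
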