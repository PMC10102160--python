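import numpy as np
import pytest
import scipy.sparse as sp

from graphtow import WeightedGraph


def random_connected_graph(rng: np.random.Generator, n: int,
                           edge_prob: float = 0.35,
                           unit_weights: bool = False) -> WeightedGraph:
    """Random Erdos-Renyi graph forced connected via a random spanning path.

    Weights are drawn in (0.2, 1.0], the range similarity maps produce.
    """
    order = rng.permutation(n)
    edges = {(min(a, b), max(a, b)) for a, b in zip(order[:-1], order[1:])}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                edges.add((i, j))
    weights = {e: 1.0 if unit_weights else float(rng.uniform(0.2, 1.0))
               for e in edges}
    return WeightedGraph.from_edges(n, [(x, y, w) for (x, y), w in weights.items()])


def path_graph(n: int, w: float = 1.0) -> WeightedGraph:
    return WeightedGraph.from_edges(n, [(i, i + 1, w) for i in range(n - 1)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def path5():
    return path_graph(5)


@pytest.fixture
def path3():
    return path_graph(3)
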