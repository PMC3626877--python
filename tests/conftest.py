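import numpy as np
import pytest

from remic.network_io import GeneNetwork, WeightedEdge


@pytest.fixture
def two_node_net():
    return GeneNetwork.from_edges([WeightedEdge("A", "B", 3.0)])


@pytest.fixture
def bridged_triangles():
    """Two triangles joined by a single bridge edge a1-b1."""
    pairs = [
        ("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
        ("b1", "b2"), ("b2", "b3"), ("b1", "b3"),
        ("a1", "b1"),
    ]
    return GeneNetwork.from_edges([WeightedEdge(a, b, 1.0) for a, b in pairs])


def random_network(n: int, p: float, seed: int, w_low=1.0, w_high=10.0,
                   connected=False) -> GeneNetwork:
    """Erdos-Renyi weighted network helper used across test modules."""
    rng = np.random.default_rng(seed)
    names = [f"g{i:03d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append(
                    WeightedEdge(names[i], names[j],
                                 float(rng.uniform(w_low, w_high)))
                )
    if connected:  # chain backbone guarantees a single component
        present = {e.key for e in edges}
        for i in range(n - 1):
            key = (names[i], names[i + 1])
            if key not in present:
                edges.append(WeightedEdge(*key, float(rng.uniform(w_low, w_high))))
    return GeneNetwork.from_edges(edges, genes=names)
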