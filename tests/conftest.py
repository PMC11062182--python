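import numpy as np
import pytest

from btsnn.connectome import Connectome, WeightedGraph, symmetrize
from btsnn.synthetic import synthetic_connectome, two_module_spec
from btsnn.topology import build_bt_network


def make_graph(edges: dict) -> WeightedGraph:
    """WeightedGraph from {(u, v): w} with nodes inferred."""
    nodes = sorted({x for e in edges for x in e})
    ew = {tuple(sorted(e)): float(w) for e, w in edges.items()}
    return WeightedGraph(nodes=nodes, edge_weights=ew)


def random_graph(rng: np.random.Generator, n_max: int = 8, p: float = 0.4):
    """Random connected-ish weighted undirected graph, >= 2 links."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        edges = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    edges[(f"n{i}", f"n{j}")] = float(rng.uniform(0.1, 5.0))
        if len(edges) >= 2:
            return make_graph(edges)


@pytest.fixture
def triangle_graph():
    return make_graph({("a", "b"): 1.0, ("b", "c"): 1.0, ("a", "c"): 1.0})


@pytest.fixture
def path_graph():
    return make_graph(
        {("a", "b"): 1.0, ("b", "c"): 2.0, ("c", "d"): 1.5}
    )


@pytest.fixture
def tiny_connectome():
    w = np.array(
        [
            [0.0, 1.0, 0.0, 0.5],
            [0.0, 0.0, 2.0, 0.0],
            [1.5, 0.0, 0.0, 1.0],
            [0.0, 0.3, 0.0, 0.0],
        ]
    )
    return Connectome(
        region_ids=["A", "B", "C", "D"],
        weights=w,
        groups={"A": "sensation", "B": "other", "C": "other", "D": "motor"},
    )


@pytest.fixture(scope="session")
def planted_connectome():
    """Two-module synthetic connectome with its ground truth."""
    return synthetic_connectome(two_module_spec(seed=1))


@pytest.fixture(scope="session")
def small_bt_network():
    """10-node single-module network with all three roles present."""
    spec = two_module_spec(sizes=(10, 5), p_within=0.8, p_between=0.05, seed=3)
    c, truth = synthetic_connectome(spec)
    nodes = [r for r in c.region_ids if truth[r] == 0]
    return build_bt_network(c, nodes, seed=0)
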