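import numpy as np
import pytest

from stentflow.geometry import make_scenario
from stentflow.network import HydraulicNetwork, Edge, assemble_network, solve_network


@pytest.fixture(scope="session")
def case_solutions():
    """All nine study cases, assembled and solved once."""
    out = {}
    for cid in range(1, 10):
        net = assemble_network(make_scenario(cid))
        out[cid] = (net, solve_network(net))
    return out


def random_test_network(seed: int, n_nodes: int = 50) -> HydraulicNetwork:
    """Random connected two-reservoir network for solver oracle checks.

    A random spanning tree guarantees connectivity; extra chords add
    cycles.  Conductances are log-uniform over four decades.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, n_nodes + 1))
    edges = []

    def g() -> float:
        return float(10.0 ** rng.uniform(-8, -4))

    def make_edge(a: int, b: int) -> Edge:
        return Edge(a, b, g(), "intra_pipe", 1, 1e-3, 1e-6)

    order = rng.permutation(n)
    for i in range(1, n):
        a = int(order[rng.integers(0, i)])
        edges.append(make_edge(a, int(order[i])))
    for _ in range(int(rng.integers(n, 3 * n))):
        a, b = rng.integers(0, n, size=2)
        if a != b:
            edges.append(make_edge(int(a), int(b)))
    return HydraulicNetwork(
        n_nodes=n,
        edges=edges,
        reservoir_pressures={0: 97.8, 1: 0.0},
        node_labels=[f"n{i}" for i in range(n)],
        station_positions=np.empty(0),
        segment_bounds=np.empty((0, 2)),
        segment_holes=[],
    )
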