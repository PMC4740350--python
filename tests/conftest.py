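import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netprox.interactome import Interactome, build_degree_bins
from netprox.fixtures import FixtureSpec, standard_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def path5():
    return Interactome(nx.path_graph(["1", "2", "3", "4", "5"]))


@pytest.fixture
def path4():
    return Interactome(nx.path_graph(["1", "2", "3", "4"]))


@pytest.fixture
def c6():
    return Interactome(nx.cycle_graph([f"v{i}" for i in range(6)]))


@pytest.fixture
def star5():
    return Interactome(nx.star_graph(["h", "l1", "l2", "l3", "l4"]))


@pytest.fixture
def k4():
    return Interactome(nx.complete_graph(["a", "b", "c", "d"]))


@pytest.fixture(scope="session")
def bench():
    """The seed-pinned benchmark study shared across heavier tests."""
    return standard_fixture(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def bench_bins(bench):
    return build_degree_bins(bench.network)


def random_connected_graph(rng: np.random.Generator, n_max: int = 20) -> Interactome:
    """Small random connected graph for oracle-equivalence tests."""
    n = int(rng.integers(4, n_max + 1))
    p = float(rng.uniform(0.15, 0.5))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        for a, b in zip(comps, comps[1:]):
            g.add_edge(a[0], b[0])
    return Interactome(nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes}))
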