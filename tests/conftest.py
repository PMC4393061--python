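import pytest

from rnadual.enumeration import enumerate_dual_graphs
from rnadual.multigraph import Multigraph


@pytest.fixture(scope="session")
def catalog2():
    return enumerate_dual_graphs(2)


@pytest.fixture(scope="session")
def catalog3():
    return enumerate_dual_graphs(3)


@pytest.fixture(scope="session")
def catalog4():
    return enumerate_dual_graphs(4)


@pytest.fixture(scope="session")
def catalog5():
    return enumerate_dual_graphs(5)


@pytest.fixture
def loop_double():
    """Order-2 dual graph: a loop at u plus a double edge u-v."""
    return Multigraph(["u", "v"], [("u", "u"), ("u", "v"), ("u", "v")])


@pytest.fixture
def triangle():
    return Multigraph([0, 1, 2], [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3():
    return Multigraph([0, 1, 2], [(0, 1), (1, 2)])


def random_multigraph(rng, n_max=5, m_max=7):
    """Random small multigraph for property tests (seeded rng)."""
    n = int(rng.integers(1, n_max + 1))
    m = int(rng.integers(0, m_max + 1))
    edges = []
    for _ in range(m):
        u = int(rng.integers(n))
        v = int(rng.integers(n))
        edges.append((u, v))
    return Multigraph(range(n), edges)
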