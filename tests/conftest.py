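import itertools

import networkx as nx
import pytest

from netmoa.network import new_network


@pytest.fixture
def bridged_cliques():
    """Two 5-cliques joined by a single bridge edge A0-B0."""
    edges = []
    a = [f"A{i}" for i in range(5)]
    b = [f"B{i}" for i in range(5)]
    for grp in (a, b):
        edges += list(itertools.combinations(grp, 2))
    edges.append(("A0", "B0"))
    return new_network(edges), frozenset(a), frozenset(b)


@pytest.fixture
def clique6():
    nodes = [f"K{i}" for i in range(6)]
    return new_network(itertools.combinations(nodes, 2)), frozenset(nodes)


@pytest.fixture
def path10():
    nodes = [f"N{i}" for i in range(10)]
    return new_network(zip(nodes, nodes[1:]))


@pytest.fixture(scope="session")
def toy_study(tmp_path_factory):
    """A complete synthetic study on disk, built once per session."""
    from netmoa.synthetic import make_fixtures

    outdir = tmp_path_factory.mktemp("toy_study")
    paths, truth = make_fixtures(outdir, rng_seed=7)
    return paths, truth


def er_graph(n, p, seed):
    """Seeded Erdős–Rényi graph over string node labels."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes})
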