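from itertools import combinations

import networkx as nx
import pytest

from gammanet.gamma_cluster import ClusterSearchParams
from gammanet.graph_core import add_base_edge, add_base_node, new_graph
from gammanet.hierarchy import GammaSchedule, create_multilevel_clusters
from gammanet.tree_transform import tree_transformation


def clique(prefix: str, n: int, graph=None) -> nx.Graph:
    """Add a complete graph on nodes ``<prefix>0 .. <prefix>{n-1}``."""
    graph = graph if graph is not None else new_graph()
    for u, v in combinations([f"{prefix}{i}" for i in range(n)], 2):
        add_base_edge(graph, u, v)
    return graph


def as_base(graph: nx.Graph) -> nx.Graph:
    """Relabel an arbitrary networkx graph into package conventions."""
    out = new_graph()
    for n in sorted(graph.nodes()):
        add_base_node(out, f"v{n:03d}" if isinstance(n, int) else str(n))
    for u, v in graph.edges():
        fu = f"v{u:03d}" if isinstance(u, int) else str(u)
        fv = f"v{v:03d}" if isinstance(v, int) else str(v)
        add_base_edge(out, fu, fv)
    return out


@pytest.fixture
def two_k4_bridge() -> nx.Graph:
    """Two K4s joined by exactly one edge — the worked hierarchy fixture."""
    g = clique("a", 4)
    g = clique("b", 4, g)
    add_base_edge(g, "a0", "b0")
    return g


@pytest.fixture
def two_k4_hierarchy(two_k4_bridge):
    params = ClusterSearchParams(gamma=0.5, min_size=2, restarts=20, seed=11)
    return create_multilevel_clusters(two_k4_bridge, GammaSchedule((0.5, 0.7)), params)


@pytest.fixture
def two_k4_tree(two_k4_hierarchy):
    return tree_transformation(two_k4_hierarchy, seed=5)


@pytest.fixture
def edgeless_graph() -> nx.Graph:
    g = new_graph()
    for i in range(10):
        add_base_node(g, f"v{i}")
    return g
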