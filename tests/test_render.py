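import re

import networkx as nx
import pytest

from gammanet import graph_core as gc
from gammanet.gamma_cluster import ClusterSearchParams
from gammanet.hierarchy import GammaSchedule, create_multilevel_clusters
from gammanet.layout import LayoutParams, force_layout
from gammanet.render import (StyleMap, cluster_internal_edges, degree_color,
                             highlight_neighbors, level0_graph, render_svg,
                             uncovered_base_edges)
from gammanet.tree_transform import tree_transformation

from conftest import as_base, clique


@pytest.fixture()
def k4_external_scene():
    """Level-1 cluster over a K4 with one external edge from a member."""
    g = clique("a", 4)
    gc.add_base_edge(g, "a0", "out")
    h = create_multilevel_clusters(
        g, GammaSchedule((0.9,)),
        ClusterSearchParams(gamma=0.9, min_size=3, restarts=10, seed=0))
    t = tree_transformation(h, seed=0)
    return t, force_layout(t, LayoutParams(seed=0, max_iterations=60))


class TestRenderSvg:
    def test_element_counts(self, k4_external_scene, tmp_path):
        t, res = k4_external_scene
        path = tmp_path / "scene.svg"
        render_svg(t, res, path)
        text = path.read_text()
        nodes = re.findall(r'class="node ', text)
        edges = re.findall(r'class="edge ', text)
        # 5 base dots + 1 cluster square; root hidden
        assert len(nodes) == 6
        # tree edges not incident to the root: 4 membership + a0-out
        assert len(edges) == 5

    def test_byte_identical_rerenders(self, k4_external_scene, tmp_path):
        t, res = k4_external_scene
        render_svg(t, res, tmp_path / "a.svg")
        render_svg(t, res, tmp_path / "b.svg")
        assert (tmp_path / "a.svg").read_bytes() == (tmp_path / "b.svg").read_bytes()

    def test_highlight_elements(self, k4_external_scene, tmp_path):
        t, res = k4_external_scene
        hl = set(list(cluster_internal_edges(t, t.hierarchy.cluster_nodes(1)[0]))[:3])
        path = tmp_path / "h.svg"
        render_svg(t, res, path, highlights=hl)
        assert len(re.findall(r'class="highlight"', path.read_text())) == 3

    def test_missing_position_names_node(self, k4_external_scene, tmp_path):
        t, res = k4_external_scene
        broken = res.positions.copy()
        broken.pop("a0")
        res2 = type(res)(positions=broken, iterations_run=res.iterations_run,
                         converged=res.converged, params=res.params)
        with pytest.raises(ValueError, match="a0"):
            render_svg(t, res2, tmp_path / "x.svg")

    def test_root_never_drawn(self, k4_external_scene, tmp_path):
        t, res = k4_external_scene
        path = tmp_path / "r.svg"
        render_svg(t, res, path)
        assert t.root not in path.read_text()


class TestStyleMap:
    def test_cluster_size_strictly_increasing_with_level(self):
        s = StyleMap()
        sizes = [s.cluster_half_size(lvl) for lvl in range(5)]
        assert all(b > a for a, b in zip(sizes, sizes[1:]))

    def test_bad_bins_rejected(self):
        with pytest.raises(ValueError):
            StyleMap(n_bins=99)


class TestDegreeColor:
    def test_regular_graph_is_monochrome(self):
        g = as_base(nx.cycle_graph(8))
        assert len(set(degree_color(g).values())) == 1

    def test_star_center_tops_the_ramp(self):
        g = as_base(nx.star_graph(9))
        colors = degree_color(g)
        style = StyleMap()
        assert colors["v000"] == style.palette[-1]
        leaf_colors = {c for n, c in colors.items() if n != "v000"}
        assert len(leaf_colors) == 1 and leaf_colors != {style.palette[-1]}

    def test_empty_graph(self):
        assert degree_color(nx.Graph()) == {}

    def test_equal_degrees_equal_colors(self):
        g = as_base(nx.gnp_random_graph(30, 0.2, seed=3))
        colors = degree_color(g)
        by_degree = {}
        for n, c in colors.items():
            by_degree.setdefault(g.degree(n), set()).add(c)
        assert all(len(cs) == 1 for cs in by_degree.values())


class TestDrillDown:
    def test_base_node_neighbors(self, k4_external_scene):
        t, _ = k4_external_scene
        assert len(highlight_neighbors(t, "a0")) == 4  # 3 clique + 1 external

    def test_isolated_base_node(self, edgeless_graph):
        h = create_multilevel_clusters(edgeless_graph)
        t = tree_transformation(h, seed=0)
        assert highlight_neighbors(t, "v0") == set()

    def test_cluster_node_connections(self, k4_external_scene):
        t, _ = k4_external_scene
        (cn,) = t.hierarchy.cluster_nodes(1)
        edges = highlight_neighbors(t, cn)
        # 4 membership edges + the member-to-outside original edge
        assert frozenset(("a0", "out")) in edges
        assert len(edges) == 5

    def test_cluster_internal_edges_counts(self, k4_external_scene, two_k4_tree):
        t, _ = k4_external_scene
        (cn,) = t.hierarchy.cluster_nodes(1)
        assert len(cluster_internal_edges(t, cn)) == 6  # K4
        (top,) = two_k4_tree.hierarchy.cluster_nodes(2)
        assert len(cluster_internal_edges(two_k4_tree, top)) == 1

    def test_non_cluster_rejected(self, k4_external_scene):
        t, _ = k4_external_scene
        with pytest.raises(TypeError):
            cluster_internal_edges(t, "a0")

    def test_completeness_reconstructs_original_edges(self, two_k4_tree):
        t = two_k4_tree
        recovered = set()
        for cn in t.hierarchy.cluster_nodes(1):
            recovered |= cluster_internal_edges(t, cn)
        recovered |= uncovered_base_edges(t)
        original = {frozenset(e) for e in level0_graph(t).edges()}
        assert recovered == original

    def test_visible_edge_economy(self, two_k4_tree):
        t = two_k4_tree
        shown = t.tree_edges() & {frozenset(e)
                                  for e in t.hierarchy.graph.edges()}
        assert len(shown) < t.hierarchy.graph.number_of_edges()
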