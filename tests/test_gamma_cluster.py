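import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gammanet import gamma_cluster as gcl
from gammanet.graph_core import add_base_edge, add_base_node, new_graph
from gammanet.synthetic import PlantedPartitionSpec, planted_partition

from conftest import as_base, clique


class TestGammaDensity:
    def test_complete_graph(self):
        g = clique("a", 4)
        assert gcl.gamma_density(g, g.nodes()) == 1.0

    def test_path_of_three(self):
        g = as_base(nx.path_graph(3))
        assert gcl.gamma_density(g, g.nodes()) == pytest.approx(2 / 3)

    def test_singleton_convention(self):
        g = as_base(nx.path_graph(3))
        assert gcl.gamma_density(g, ["v000"]) == 1.0

    def test_unknown_member(self):
        with pytest.raises(KeyError):
            gcl.gamma_density(as_base(nx.path_graph(3)), ["nope", "v000"])


class TestIsGammaCluster:
    @pytest.mark.parametrize("gamma,expected", [(1.0, True)])
    def test_clique(self, gamma, expected):
        g = clique("a", 4)
        assert gcl.is_gamma_cluster(g, g.nodes(), gamma) is expected

    @pytest.mark.parametrize("gamma,expected", [(0.7, False), (0.5, True)])
    def test_path(self, gamma, expected):
        g = as_base(nx.path_graph(3))
        assert gcl.is_gamma_cluster(g, g.nodes(), gamma) is expected

    @given(g1=st.floats(0, 1), g2=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_gamma(self, g1, g2):
        """Satisfying a stricter density implies satisfying a looser one."""
        g = as_base(nx.cycle_graph(5))
        lo, hi = min(g1, g2), max(g1, g2)
        if gcl.is_gamma_cluster(g, g.nodes(), hi):
            assert gcl.is_gamma_cluster(g, g.nodes(), lo)


class TestExactOracle:
    def test_k5_clique(self):
        g = clique("a", 5)
        assert gcl.max_gamma_clique_exact(g, 1.0) == set(g.nodes())

    def test_five_cycle_gamma_one_is_an_edge(self):
        g = as_base(nx.cycle_graph(5))
        result = gcl.max_gamma_clique_exact(g, 1.0)
        assert len(result) == 2 and g.has_edge(*result)

    def test_five_cycle_gamma_half_is_everything(self):
        # 5 of 10 pairs adjacent: density exactly 0.5
        g = as_base(nx.cycle_graph(5))
        assert gcl.max_gamma_clique_exact(g, 0.5) == set(g.nodes())

    def test_size_guard(self):
        with pytest.raises(ValueError):
            gcl.max_gamma_clique_exact(as_base(nx.path_graph(25)), 1.0)


class TestConstructDsubg:
    def test_k6_plus_pendant(self):
        g = clique("a", 6)
        add_base_edge(g, "a0", "pendant")
        c = gcl.construct_dsubg(g, gcl.ClusterSearchParams(
            gamma=1.0, min_size=3, restarts=20, seed=1))
        assert c.members == frozenset(f"a{i}" for i in range(6))
        assert c.density == 1.0

    def test_two_k5_matching_returns_one_clique(self):
        g = clique("a", 5)
        g = clique("b", 5, g)
        for i in range(5):
            add_base_edge(g, f"a{i}", f"b{i}")
        c = gcl.construct_dsubg(g, gcl.ClusterSearchParams(
            gamma=1.0, min_size=3, restarts=20, seed=2))
        assert c.members in (frozenset(f"a{i}" for i in range(5)),
                             frozenset(f"b{i}" for i in range(5)))

    def test_edgeless_graph_yields_nothing(self):
        g = new_graph()
        for i in range(10):
            add_base_node(g, f"v{i}")
        assert gcl.construct_dsubg(g, gcl.ClusterSearchParams(
            gamma=0.5, min_size=3, restarts=5, seed=0)) is None

    def test_emitted_cluster_satisfies_density(self):
        g = as_base(nx.gnp_random_graph(30, 0.3, seed=8))
        c = gcl.construct_dsubg(g, gcl.ClusterSearchParams(
            gamma=0.6, min_size=3, restarts=10, seed=3))
        assert c is not None
        assert gcl.is_gamma_cluster(g, c.members, 0.6)

    def test_seed_determinism(self):
        g = as_base(nx.gnp_random_graph(25, 0.4, seed=9))
        p = gcl.ClusterSearchParams(gamma=0.7, min_size=3, restarts=15, seed=42)
        assert gcl.construct_dsubg(g, p) == gcl.construct_dsubg(g, p)


class TestCreateClusters:
    def test_two_disjoint_k4s_plus_isolated(self):
        g = clique("a", 4)
        g = clique("b", 4, g)
        add_base_node(g, "iso")
        clusters = gcl.create_clusters(g, gcl.ClusterSearchParams(
            gamma=0.5, min_size=3, restarts=20, seed=4))
        found = sorted(sorted(c.members) for c in clusters)
        assert found == [["a0", "a1", "a2", "a3"], ["b0", "b1", "b2", "b3"]]

    def test_sparse_tree_has_no_dense_clusters(self):
        g = as_base(nx.random_labeled_tree(15, seed=6))
        assert gcl.create_clusters(g, gcl.ClusterSearchParams(
            gamma=0.9, min_size=3, restarts=10, seed=0)) == []

    def test_planted_partition_recovery(self):
        graph, block = planted_partition(PlantedPartitionSpec(
            n_blocks=3, block_size=10, p_in=0.9, p_out=0.02, seed=13))
        clusters = gcl.create_clusters(graph, gcl.ClusterSearchParams(
            gamma=0.7, min_size=4, restarts=30, seed=13))
        assert len(clusters) == 3
        truth = [{n for n, b in block.items() if b == k} for k in range(3)]
        for t in truth:
            jac = max(len(t & set(c.members)) / len(t | set(c.members))
                      for c in clusters)
            assert jac >= 0.9

    def test_clusters_are_disjoint_and_dense(self):
        g = as_base(nx.gnp_random_graph(60, 0.25, seed=21))
        clusters = gcl.create_clusters(g, gcl.ClusterSearchParams(
            gamma=0.6, min_size=3, restarts=10, seed=5))
        seen: set[str] = set()
        for c in clusters:
            assert not (seen & c.members)
            seen |= c.members
            assert gcl.is_gamma_cluster(g, c.members, c.gamma_used)

    def test_determinism(self):
        g = as_base(nx.gnp_random_graph(40, 0.3, seed=17))
        p = gcl.ClusterSearchParams(gamma=0.6, min_size=3, restarts=10, seed=99)
        a = gcl.create_clusters(g, p)
        b = gcl.create_clusters(g, p)
        assert [c.members for c in a] == [c.members for c in b]


class TestOracleDominance:
    def test_never_exceeds_and_mostly_matches(self):
        rng = random.Random(0)
        matches = 0
        trials = 40
        for t in range(trials):
            n = rng.randint(5, 12)
            p = rng.uniform(0.3, 0.8)
            g = as_base(nx.gnp_random_graph(n, p, seed=1000 + t))
            exact = gcl.max_gamma_clique_exact(g, 1.0)
            c = gcl.construct_dsubg(g, gcl.ClusterSearchParams(
                gamma=1.0, min_size=2, restarts=50, seed=t))
            size = len(c.members) if c else 1
            assert size <= len(exact)
            matches += size == len(exact)
        assert matches >= 0.9 * trials
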