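"""Multilevel cluster hierarchy construction.

Starting from a flat graph (all nodes at level 0), γ-clusters are detected
level by level: the clusters of level i−1 become ordinary nodes at level i,
two cluster nodes are joined by an *intercluster* edge whenever any edge
exists between their member sets one level below, and every cluster node is
joined to each of its members by a *membership* edge. Each level i uses its
own density requirement γ_i, supplied by a :class:`GammaSchedule`; because
the working graph densifies as clustering proceeds, the schedule should be
non-decreasing (the default is 0.5 for the first level and 0.7 afterwards).

Construction stops when a level yields no clusters, or when it yields a
single cluster (nothing left to merge). Nodes that no cluster absorbed stay
at their level; they keep their original edges and are handled later by the
tree transformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx

from . import graph_core as gcore
from .gamma_cluster import (Cluster, ClusterSearchParams, create_clusters,
                            gamma_density, validate_gamma)

logger = logging.getLogger(__name__)

DEFAULT_SCHEDULE = (0.5, 0.7)


@dataclass(frozen=True)
class GammaSchedule:
    """Per-level γ values, level 1 first; the last value repeats if the
    hierarchy grows deeper than the schedule."""

    values: tuple[float, ...] = DEFAULT_SCHEDULE

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("schedule must contain at least one gamma value")
        object.__setattr__(self, "values", tuple(validate_gamma(v) for v in self.values))
        if any(b < a for a, b in zip(self.values, self.values[1:])):
            logger.warning(
                "gamma schedule %s is not non-decreasing; the working graph "
                "densifies with level, a growing schedule is recommended",
                self.values,
            )

    def gamma_for(self, level: int) -> float:
        if level < 1:
            raise ValueError("levels are 1-based")
        return self.values[min(level, len(self.values)) - 1]


@dataclass
class Hierarchy:
    """Layered graph: base nodes, cluster nodes, intercluster edges and
    membership edges, plus the detected clusters and the membership map
    (node -> id of the cluster node one level above containing it)."""

    graph: nx.Graph
    clusters: list[Cluster] = field(default_factory=list)
    membership: dict[str, str] = field(default_factory=dict)
    n_levels: int = 0

    def cluster_nodes(self, level: int | None = None) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True)
            if d["kind"] == gcore.KIND_CLUSTER
            and (level is None or d["level"] == level)
        )

    def members_of(self, cluster_node: str) -> set[str]:
        if self.graph.nodes[cluster_node]["kind"] != gcore.KIND_CLUSTER:
            raise TypeError(f"{cluster_node!r} is not a cluster node")
        return {
            v for v in self.graph[cluster_node]
            if self.graph.edges[cluster_node, v]["edge_type"] == gcore.EDGE_MEMBERSHIP
            and self.graph.nodes[v]["level"]
            == self.graph.nodes[cluster_node]["level"] - 1
        }

    def base_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d["kind"] == gcore.KIND_BASE)


def create_multilevel_clusters(
    graph: nx.Graph,
    schedule: GammaSchedule | None = None,
    params: ClusterSearchParams | None = None,
) -> Hierarchy:
    """Build the full multilevel hierarchy bottom-up.

    ``graph`` must contain only base nodes at level 0. ``params.gamma`` is
    ignored; the schedule supplies γ per level. Deterministic under a fixed
    ``params.seed``.
    """
    schedule = schedule or GammaSchedule()
    params = params or ClusterSearchParams(gamma=schedule.gamma_for(1))
    bad = [n for n, d in graph.nodes(data=True)
           if d.get("level", 0) != 0 or d.get("kind", gcore.KIND_BASE) != gcore.KIND_BASE]
    if bad:
        raise ValueError(f"input must contain only level-0 base nodes; offending: {sorted(bad)[:5]}")

    h_graph = gcore.ensure_attributes(graph.copy())
    hierarchy = Hierarchy(graph=h_graph)

    level_graph = graph.copy()  # working graph of the level being clustered
    level = 1
    while True:
        gamma_i = schedule.gamma_for(level)
        p = replace(params, gamma=gamma_i,
                    seed=(params.seed + 7919 * level) % (2**31))
        clusters = create_clusters(level_graph, p)
        if not clusters:
            break
        clusters = sorted(clusters, key=lambda c: tuple(c.sorted_members()))
        ids = gcore.fresh_cluster_ids(h_graph.nodes(), level, len(clusters))
        for cid, cluster in zip(ids, clusters):
            h_graph.add_node(cid, level=level, kind=gcore.KIND_CLUSTER)
            for m in cluster.sorted_members():
                h_graph.add_edge(cid, m, edge_type=gcore.EDGE_MEMBERSHIP)
                hierarchy.membership[m] = cid
            hierarchy.clusters.append(cluster)
        # intercluster edges: witnessed by any edge one level below
        next_graph = nx.Graph()
        for cid in ids:
            next_graph.add_node(cid, level=level, kind=gcore.KIND_CLUSTER)
        for i, ci in enumerate(clusters):
            for j in range(i + 1, len(clusters)):
                cj = clusters[j]
                if any(level_graph.has_edge(u, v)
                       for u in ci.members for v in cj.members):
                    h_graph.add_edge(ids[i], ids[j], edge_type=gcore.EDGE_INTERCLUSTER)
                    next_graph.add_edge(ids[i], ids[j],
                                        edge_type=gcore.EDGE_INTERCLUSTER)
        hierarchy.n_levels = level
        logger.info("level %d: %d cluster(s) at gamma=%.2f", level, len(clusters), gamma_i)
        if len(clusters) == 1:
            break
        level_graph = next_graph
        level += 1
    return hierarchy


def level_subgraph(hierarchy: Hierarchy, level: int) -> nx.Graph:
    """Induced graph of the nodes at exactly ``level`` with that level's
    inter-node edges (membership edges excluded)."""
    if not 0 <= level <= hierarchy.n_levels:
        raise ValueError(
            f"level {level} out of range [0, {hierarchy.n_levels}]")
    nodes = [n for n, d in hierarchy.graph.nodes(data=True) if d["level"] == level]
    sub = nx.Graph()
    for n in nodes:
        sub.add_node(n, **hierarchy.graph.nodes[n])
    for u, v, d in hierarchy.graph.edges(nodes, data=True):
        if (u in sub and v in sub
                and d["edge_type"] != gcore.EDGE_MEMBERSHIP):
            sub.add_edge(u, v, **d)
    return sub


def mean_level_density(hierarchy: Hierarchy, level: int) -> float:
    """Whole-subgraph density of one level (convention: ≤ 1 node → 1.0)."""
    sub = level_subgraph(hierarchy, level)
    return gamma_density(sub, sub.nodes())


def write_hierarchy_graphml(hierarchy: Hierarchy, path) -> None:
    gcore.write_graphml(hierarchy.graph, path)
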