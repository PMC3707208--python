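"""Transformation of the cluster hierarchy into a rooted layout tree.

A hidden root node is attached to every cluster node at the highest level.
A breadth-first search from the root over the *full* hierarchy graph (base,
intercluster and membership edges alike) assigns each node its distance;
each node's tree parent is a neighbour one step closer to the root. When a
node is a member of a cluster one level above, that cluster is preferred as
the parent (it is virtually always distance-minimal — the preference is
applied only when it is, so depths always equal BFS distances). Remaining
ties are broken uniformly at random under a run-wide seed.

Connected components containing no cluster at all are unreachable from the
root; each such orphan component is attached to the root by one synthetic
edge at its lexicographically smallest node and flagged, so the renderer can
style it.
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from . import graph_core as gcore
from .hierarchy import Hierarchy


@dataclass
class LayoutTree:
    """Rooted shortest-path tree over a hierarchy.

    ``parent`` maps every non-root node to its tree parent; ``depth`` maps
    every node (root included, depth 0) to its BFS distance from the root.
    ``orphan_attachments`` lists nodes hooked to the root by a synthetic
    edge because their component contains no cluster.
    """

    root: str
    parent: dict[str, str]
    depth: dict[str, int]
    hierarchy: Hierarchy
    orphan_attachments: set[str] = field(default_factory=set)

    def tree_edges(self) -> set[frozenset[str]]:
        return {frozenset((child, par)) for child, par in self.parent.items()}

    def children(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {n: [] for n in self.depth}
        for child, par in self.parent.items():
            out[par].append(child)
        for lst in out.values():
            lst.sort()
        return out

    def height(self) -> int:
        return max(self.depth.values(), default=0)

    def node_kind(self, node: str) -> str:
        if node == self.root:
            return gcore.KIND_ROOT
        return self.hierarchy.graph.nodes[node]["kind"]

    def node_level(self, node: str) -> int:
        if node == self.root:
            return self.hierarchy.n_levels
        return self.hierarchy.graph.nodes[node]["level"]


def _unique_root_id(graph: nx.Graph) -> str:
    rid = "ROOT"
    while rid in graph:
        rid = "_" + rid
    return rid


def tree_transformation(hierarchy: Hierarchy, seed: int = 0) -> LayoutTree:
    """BFS shortest-path tree of the hierarchy from a hidden root."""
    g = hierarchy.graph
    root = _unique_root_id(g)
    work = g.copy()
    work.add_node(root, level=hierarchy.n_levels, kind=gcore.KIND_ROOT)
    top = hierarchy.cluster_nodes(hierarchy.n_levels) if hierarchy.n_levels else []
    for cid in top:
        work.add_edge(root, cid, edge_type=gcore.EDGE_MEMBERSHIP)

    # orphan components: no path to the root through any cluster
    orphans: set[str] = set()
    reached = set(nx.node_connected_component(work, root)) if work.number_of_nodes() else {root}
    for comp in nx.connected_components(g):
        if comp & reached:
            continue
        rep = min(comp)
        orphans.add(rep)
        work.add_edge(root, rep, edge_type=gcore.EDGE_MEMBERSHIP)

    depth: dict[str, int] = {root: 0}
    order: list[str] = []
    queue = deque([root])
    while queue:
        u = queue.popleft()
        order.append(u)
        for v in sorted(work[u]):
            if v not in depth:
                depth[v] = depth[u] + 1
                queue.append(v)

    rng = random.Random(seed)
    parent: dict[str, str] = {}
    for node in order:
        if node == root:
            continue
        d = depth[node]
        cluster = hierarchy.membership.get(node)
        if cluster is not None and depth.get(cluster) == d - 1:
            parent[node] = cluster
            continue
        if node in orphans or (node in top and d == 1):
            parent[node] = root
            continue
        options = sorted(v for v in work[node] if depth.get(v) == d - 1)
        parent[node] = options[0] if len(options) == 1 else rng.choice(options)
    return LayoutTree(root=root, parent=parent, depth=depth,
                      hierarchy=hierarchy, orphan_attachments=orphans)


def hidden_edges(tree: LayoutTree) -> set[frozenset[str]]:
    """Hierarchy edges not shown by the tree — the complement drill-down
    views reveal on demand. Together with the tree edges they partition the
    hierarchy's edge set (synthetic root edges are tree-only)."""
    all_edges = {frozenset((u, v)) for u, v in tree.hierarchy.graph.edges()}
    return all_edges - tree.tree_edges()


def write_tree_graphml(tree: LayoutTree, path) -> None:
    """Full hierarchy as GraphML with a boolean ``in_tree`` edge mark."""
    out = tree.hierarchy.graph.copy()
    gcore.ensure_attributes(out)
    shown = tree.tree_edges()
    for u, v, d in out.edges(data=True):
        d["in_tree"] = frozenset((u, v)) in shown
    nx.write_graphml(out, str(path))


def write_parent_map(tree: LayoutTree, path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tparent\tdepth\n")
        for node in sorted(tree.parent):
            fh.write(f"{node}\t{tree.parent[node]}\t{tree.depth[node]}\n")
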