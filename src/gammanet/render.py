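"""Semantic rendering and drill-down queries.

The default view draws only the tree: base nodes as dots coloured by their
degree in the original graph, cluster nodes as squares growing with level,
and the hidden root not at all. Most original edges are therefore absent
from the picture; the two drill-down queries recover them on demand:

* :func:`highlight_neighbors` — the edges between a selected node and its
  direct neighbours (for a cluster node, every connection to and out of the
  cluster),
* :func:`cluster_internal_edges` — the level-below edges among a cluster's
  members, i.e. the structure the cluster symbol stands for.

Output is plain SVG assembled with fixed number formatting, so the same
scene always serializes to the same bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from . import graph_core as gcore
from .tree_transform import LayoutTree
from .layout import LayoutResult

DEFAULT_PALETTE = ("#2166ac", "#67a9cf", "#d1e5f0", "#ef8a62", "#b2182b")


@dataclass(frozen=True)
class StyleMap:
    """Visual encoding: degree-binned colours for base nodes, level-scaled
    squares for cluster nodes, per-type edge colours and a highlight style.
    Cluster size strictly increases with level; the root is never drawn."""

    palette: tuple[str, ...] = DEFAULT_PALETTE
    n_bins: int = 5
    base_radius: float = 3.0
    cluster_size_step: float = 3.0
    cluster_color: str = "#4d9221"
    edge_color: str = "#bbbbbb"
    membership_edge_color: str = "#999999"
    highlight_color: str = "#e31a1c"
    background: str = "#ffffff"

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.n_bins > len(self.palette):
            raise ValueError("n_bins must be between 1 and the palette size")
        if self.base_radius <= 0 or self.cluster_size_step <= 0:
            raise ValueError("node sizes must be positive")

    def cluster_half_size(self, level: int) -> float:
        return self.base_radius + self.cluster_size_step * level


def degree_color(graph: nx.Graph, style: StyleMap | None = None) -> dict[str, str]:
    """Quantile-binned colour per node from its degree in the original
    (level-0) graph; equal degrees always share a colour."""
    style = style or StyleMap()
    nodes = sorted(graph.nodes())
    if not nodes:
        return {}
    degrees = np.array([graph.degree(n) for n in nodes], dtype=float)
    qs = np.quantile(degrees, np.linspace(0, 1, style.n_bins + 1)[1:-1])
    bins = np.searchsorted(qs, degrees, side="left")
    return {n: style.palette[int(b)] for n, b in zip(nodes, bins)}


# --------------------------------------------------------------------------
# Drill-down queries
# --------------------------------------------------------------------------


def _level_below_edges(tree: LayoutTree, members: set[str]) -> set[frozenset[str]]:
    g = tree.hierarchy.graph
    out = set()
    for u in members:
        for v in g[u]:
            if g.edges[u, v]["edge_type"] != gcore.EDGE_MEMBERSHIP and v in members:
                out.add(frozenset((u, v)))
    return out


def highlight_neighbors(tree: LayoutTree, node: str) -> set[frozenset[str]]:
    """Edges between ``node`` and its direct neighbours.

    Base node: its original-graph edges. Cluster node: every hierarchy edge
    incident to it (membership, intercluster, parent membership) plus the
    level-below edges leaving the cluster from its members.
    """
    g = tree.hierarchy.graph
    if node not in g:
        raise KeyError(f"node {node!r} not in hierarchy")
    kind = g.nodes[node]["kind"]
    if kind == gcore.KIND_BASE:
        return {frozenset((node, v)) for v in g[node]
                if g.edges[node, v]["edge_type"] == gcore.EDGE_BASE}
    members = tree.hierarchy.members_of(node)
    edges = {frozenset((node, v)) for v in g[node]}
    for u in members:
        for v in g[u]:
            if (g.edges[u, v]["edge_type"] != gcore.EDGE_MEMBERSHIP
                    and v not in members):
                edges.add(frozenset((u, v)))
    return edges


def cluster_internal_edges(tree: LayoutTree, cluster_node: str) -> set[frozenset[str]]:
    """The level-below edges among the members of ``cluster_node`` — the
    real connectivity its symbol replaces."""
    members = tree.hierarchy.members_of(cluster_node)  # raises on non-cluster
    return _level_below_edges(tree, members)


def uncovered_base_edges(tree: LayoutTree) -> set[frozenset[str]]:
    """Original edges interior to no level-1 cluster: edges crossing cluster
    boundaries or touching unclustered (orphan) nodes."""
    g = tree.hierarchy.graph
    membership = tree.hierarchy.membership
    out = set()
    for u, v, d in g.edges(data=True):
        if d["edge_type"] != gcore.EDGE_BASE:
            continue
        cu, cv = membership.get(u), membership.get(v)
        if cu is None or cu != cv:
            out.add(frozenset((u, v)))
    return out


# --------------------------------------------------------------------------
# SVG rendering
# --------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def render_svg(
    tree: LayoutTree,
    layout: LayoutResult,
    path: str | Path,
    style: StyleMap | None = None,
    highlights: Iterable[frozenset[str]] | None = None,
) -> None:
    """Write the scene as SVG: one element per visible node and tree edge,
    highlight edges on top in their own style, root (and its synthetic
    edges) omitted. Byte-identical output for identical scenes."""
    style = style or StyleMap()
    positions = layout.positions
    missing = [n for n in tree.depth if n not in positions]
    if missing:
        raise ValueError(f"node {missing[0]!r} has no position")
    g = tree.hierarchy.graph
    colors = degree_color(level0_graph(tree), style)
    w, h = layout.params.area

    lines: list[str] = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(w)}" '
        f'height="{_fmt(h)}" viewBox="0 0 {_fmt(w)} {_fmt(h)}">',
        f'<rect width="100%" height="100%" fill="{style.background}"/>',
        '<g class="edges">',
    ]
    for child in sorted(tree.parent):
        par = tree.parent[child]
        if par == tree.root or child == tree.root:
            continue
        (x1, y1), (x2, y2) = positions[child], positions[par]
        etype = (g.edges[child, par]["edge_type"]
                 if g.has_edge(child, par) else gcore.EDGE_MEMBERSHIP)
        color = (style.membership_edge_color
                 if etype == gcore.EDGE_MEMBERSHIP else style.edge_color)
        lines.append(
            f'<line class="edge {etype}" x1="{_fmt(x1)}" y1="{_fmt(y1)}" '
            f'x2="{_fmt(x2)}" y2="{_fmt(y2)}" stroke="{color}" stroke-width="1"/>'
        )
    lines.append("</g>")
    if highlights:
        lines.append('<g class="highlights">')
        for edge in sorted(highlights, key=sorted):
            u, v = sorted(edge)
            if u == tree.root or v == tree.root:
                continue
            (x1, y1), (x2, y2) = positions[u], positions[v]
            lines.append(
                f'<line class="highlight" x1="{_fmt(x1)}" y1="{_fmt(y1)}" '
                f'x2="{_fmt(x2)}" y2="{_fmt(y2)}" '
                f'stroke="{style.highlight_color}" stroke-width="1.5"/>'
            )
        lines.append("</g>")
    lines.append('<g class="nodes">')
    for node in sorted(tree.depth):
        if node == tree.root:
            continue
        x, y = positions[node]
        kind = tree.node_kind(node)
        if kind == gcore.KIND_CLUSTER:
            half = style.cluster_half_size(tree.node_level(node))
            lines.append(
                f'<rect class="node cluster" x="{_fmt(x - half)}" '
                f'y="{_fmt(y - half)}" width="{_fmt(2 * half)}" '
                f'height="{_fmt(2 * half)}" fill="{style.cluster_color}" '
                f'stroke="#333333"/>'
            )
        else:
            fill = colors.get(node, style.palette[0])
            lines.append(
                f'<circle class="node base" cx="{_fmt(x)}" cy="{_fmt(y)}" '
                f'r="{_fmt(style.base_radius)}" fill="{fill}"/>'
            )
    lines.append("</g>")
    lines.append("</svg>")
    Path(path).write_text("\n".join(lines) + "\n")


def level0_graph(tree: LayoutTree) -> nx.Graph:
    """The original input graph (level-0 nodes with their base edges)."""
    g = tree.hierarchy.graph
    sub = nx.Graph()
    for n, d in g.nodes(data=True):
        if d["level"] == 0 and d["kind"] == gcore.KIND_BASE:
            sub.add_node(n, **d)
    for u, v, d in g.edges(data=True):
        if d["edge_type"] == gcore.EDGE_BASE and u in sub and v in sub:
            sub.add_edge(u, v, **d)
    return sub
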