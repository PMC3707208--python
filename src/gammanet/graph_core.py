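"""Shared graph data model and file I/O.

Graphs are plain :class:`networkx.Graph` objects with a small attribute
convention enforced on top:

* every node carries ``level`` (non-negative int; original nodes sit at
  level 0) and ``kind`` (``"base"``, ``"cluster"`` or ``"root"``),
* every edge carries ``edge_type`` (``"base"``, ``"intercluster"`` or
  ``"membership"``),
* graphs are simple and undirected; weights in input files are ignored.

Node identifiers are strings. Synthetic cluster nodes get generated names
``C<level>_<index>``, prefix-escaped until they collide with nothing.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

KIND_BASE = "base"
KIND_CLUSTER = "cluster"
KIND_ROOT = "root"

EDGE_BASE = "base"
EDGE_INTERCLUSTER = "intercluster"
EDGE_MEMBERSHIP = "membership"


class GraphInputError(ValueError):
    """Malformed or empty graph input."""


class UnsupportedFormatError(ValueError):
    """Input file is syntactically valid but not a supported graph flavour."""


def new_graph() -> nx.Graph:
    return nx.Graph()


def add_base_node(graph: nx.Graph, node: str) -> None:
    graph.add_node(str(node), level=0, kind=KIND_BASE)


def add_base_edge(graph: nx.Graph, u: str, v: str) -> None:
    add_base_node(graph, u)
    add_base_node(graph, v)
    graph.add_edge(str(u), str(v), edge_type=EDGE_BASE)


def ensure_attributes(graph: nx.Graph) -> nx.Graph:
    """Fill in missing level/kind/edge_type attributes in place."""
    for n, data in graph.nodes(data=True):
        data.setdefault("level", 0)
        data.setdefault("kind", KIND_BASE)
    for _, _, data in graph.edges(data=True):
        data.setdefault("edge_type", EDGE_BASE)
    return graph


def degree(graph: nx.Graph, node: str) -> int:
    """Number of incident edges of ``node``.

    Raises ``KeyError`` for nodes not in the graph.
    """
    if node not in graph:
        raise KeyError(f"node {node!r} not in graph")
    return graph.degree(node)


def read_edge_list(path: str | Path, delimiter: str | None = None) -> nx.Graph:
    """Read a simple undirected graph from a delimited edge list.

    Lines starting with ``#`` are comments; each remaining line must have at
    least two fields (extra fields are ignored with a warning). Duplicate
    edges, reversed duplicates and self-loops collapse/drop with a logged
    count. A file describing no nodes at all is an error.
    """
    path = Path(path)
    graph = new_graph()
    n_dupes = n_loops = n_extra = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise GraphInputError(
                    f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}"
                )
            if len(fields) > 2:
                n_extra += 1
            u, v = fields[0], fields[1]
            if u == v:
                n_loops += 1
                continue
            if graph.has_edge(u, v):
                n_dupes += 1
                continue
            add_base_edge(graph, u, v)
    if graph.number_of_nodes() == 0:
        raise GraphInputError(f"{path}: no edges found (empty graph)")
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    if n_dupes:
        logger.warning("%s: collapsed %d duplicate edge line(s)", path, n_dupes)
    if n_extra:
        logger.warning(
            "%s: ignored extra columns (e.g. weights) on %d line(s)", path, n_extra
        )
    return graph


def write_graphml(
    graph: nx.Graph,
    path: str | Path,
    positions: Mapping[str, tuple[float, float]] | None = None,
) -> None:
    """Write GraphML with level/kind node keys, edge_type edge key and
    optional x/y coordinates."""
    out = graph.copy()
    ensure_attributes(out)
    if positions is not None:
        for node, (x, y) in positions.items():
            if node in out:
                out.nodes[node]["x"] = float(x)
                out.nodes[node]["y"] = float(y)
    nx.write_graphml(out, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    """Read GraphML written by :func:`write_graphml` (or compatible).

    Missing ``level`` defaults to 0 and missing ``kind`` to ``base``; a
    directed graph element is rejected.
    """
    try:
        graph = nx.read_graphml(str(path))
    except Exception as exc:  # nx raises bare Exception subclasses on bad XML
        raise GraphInputError(f"{path}: not valid GraphML: {exc}") from exc
    if graph.is_directed():
        raise UnsupportedFormatError(f"{path}: directed graphs are not supported")
    graph = nx.Graph(graph)
    for n, data in graph.nodes(data=True):
        data["level"] = int(data.get("level", 0))
        data["kind"] = str(data.get("kind", KIND_BASE))
    for _, _, data in graph.edges(data=True):
        data["edge_type"] = str(data.get("edge_type", EDGE_BASE))
    return graph


def positions_from_graph(graph: nx.Graph) -> dict[str, tuple[float, float]]:
    """Extract x/y coordinates stored as node attributes, if any."""
    pos: dict[str, tuple[float, float]] = {}
    for n, data in graph.nodes(data=True):
        if "x" in data and "y" in data:
            pos[n] = (float(data["x"]), float(data["y"]))
    return pos


def fresh_cluster_ids(existing: Iterable[str], level: int, count: int) -> list[str]:
    """Generate ``count`` cluster-node identifiers ``C<level>_<i>`` that do
    not collide with ``existing`` names, prefix-escaping with ``_`` if an
    input node happens to use the same scheme."""
    taken = set(existing)
    prefix = "C"
    while any(f"{prefix}{level}_{i}" in taken for i in range(count)):
        prefix = "_" + prefix
    return [f"{prefix}{level}_{i}" for i in range(count)]


def induced_edge_count(graph: nx.Graph, members: Iterable[str]) -> int:
    """Number of graph edges with both endpoints in ``members``."""
    mset = set(members)
    missing = mset - set(graph.nodes())
    if missing:
        raise KeyError(f"nodes not in graph: {sorted(missing)[:5]}")
    count = 0
    for u in mset:
        for v in graph[u]:
            if v in mset:
                count += 1
    return count // 2
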