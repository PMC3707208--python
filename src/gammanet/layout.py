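"""Hierarchy-aware force-directed layout of the transformed tree.

The layout departs from a vanilla spring embedder in four ways, each aimed
at making the cluster hierarchy legible:

* **Level-dependent edge lengths** — a tree edge's target length is
  ``base_edge_length * level_factor**edge_level``, where the edge level is
  the lower of its endpoints' hierarchy levels (root-to-cluster edges take
  the top level). Higher-level edges are therefore longer and the hierarchy
  spreads outward naturally.
* **Concentric initialization** — nodes start on concentric circles around
  the hidden root, each node confined to an angular segment nested inside
  its parent's segment (sized by subtree leaf count). This seeds the
  force simulation close to the intended radial structure instead of a
  random configuration prone to tangled local minima.
* **Repulsion cutoff** — repulsive forces are ignored beyond a distance
  proportional to the drawing area, which keeps disconnected pieces from
  drifting apart indefinitely.
* **Position-averaging damping** — each node's position is the mean of its
  last ``damping_window`` raw updates, suppressing the oscillation typical
  of force simulations.

Spring forces act along tree edges proportionally to (distance − target);
repulsion is Fruchterman–Reingold style k²/d between non-adjacent pairs
within the cutoff. Excluding adjacent pairs from repulsion lets an isolated
edge equilibrate exactly at its target length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tree_transform import LayoutTree


@dataclass(frozen=True)
class LayoutParams:
    """Layout knobs, in abstract drawing units.

    area                    drawing area (width, height).
    base_edge_length        target length of the deepest (level-0) edges.
    level_factor            length multiplier per hierarchy level (> 1).
    repulsion_cutoff_fraction  repulsion range as a fraction of min(area).
    damping_window          number of recent raw positions averaged.
    max_iterations / convergence_tol
                            stop when the max per-node displacement in one
                            iteration falls below the tolerance.
    seed                    seed of the tiny symmetry-breaking jitter.
    """

    area: tuple[float, float] = (1000.0, 1000.0)
    base_edge_length: float = 30.0
    level_factor: float = 1.8
    repulsion_cutoff_fraction: float = 0.25
    damping_window: int = 3
    max_iterations: int = 300
    convergence_tol: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.area
        if w <= 0 or h <= 0:
            raise ValueError("area dimensions must be positive")
        if self.base_edge_length <= 0:
            raise ValueError("base_edge_length must be positive")
        if self.level_factor <= 1.0:
            raise ValueError("level_factor must exceed 1 (higher levels get longer edges)")
        if not 0.0 < self.repulsion_cutoff_fraction <= 1.0:
            raise ValueError("repulsion_cutoff_fraction must lie in (0, 1]")
        if self.damping_window < 1:
            raise ValueError("damping_window must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


@dataclass
class LayoutResult:
    positions: dict[str, tuple[float, float]]
    iterations_run: int
    converged: bool
    params: LayoutParams


def edge_target_length(edge_level: int, params: LayoutParams) -> float:
    """Target length of an edge at a given hierarchy level."""
    if edge_level < 0:
        raise ValueError("edge level must be non-negative")
    return params.base_edge_length * params.level_factor ** edge_level


def _node_level(tree: LayoutTree, node: str) -> int:
    hier = tree.hierarchy
    if hier is not None and hier.graph.number_of_nodes():
        return tree.node_level(node)
    # trees without a backing hierarchy: level falls out of tree depth
    return tree.height() - tree.depth[node]


def _edge_level(tree: LayoutTree, child: str, parent: str) -> int:
    if parent == tree.root or child == tree.root:
        other = child if parent == tree.root else parent
        return _node_level(tree, other)
    return min(_node_level(tree, child), _node_level(tree, parent))


def _leaf_counts(tree: LayoutTree) -> dict[str, int]:
    children = tree.children()
    counts: dict[str, int] = {}
    for node in sorted(tree.depth, key=lambda n: -tree.depth[n]):
        kids = children.get(node, [])
        counts[node] = 1 if not kids else sum(counts[k] for k in kids)
    return counts


def initial_positions(tree: LayoutTree,
                      params: LayoutParams) -> dict[str, tuple[float, float]]:
    """Concentric-circle start: root at the centre, depth-d nodes on circle
    d, each node at the bisector of its angular segment; sibling segments
    are disjoint and proportional to subtree leaf counts."""
    if not tree.depth:
        return {}
    cx, cy = params.area[0] / 2.0, params.area[1] / 2.0
    height = tree.height()
    if height == 0:
        return {tree.root: (cx, cy)}
    ring = 0.45 * min(params.area) / height
    children = tree.children()
    counts = _leaf_counts(tree)
    pos: dict[str, tuple[float, float]] = {tree.root: (cx, cy)}
    segment: dict[str, tuple[float, float]] = {tree.root: (0.0, 2.0 * math.pi)}
    stack = [tree.root]
    while stack:
        node = stack.pop()
        lo, hi = segment[node]
        kids = children.get(node, [])
        total = sum(counts[k] for k in kids)
        start = lo
        for kid in kids:
            width = (hi - lo) * counts[kid] / total
            segment[kid] = (start, start + width)
            angle = start + width / 2.0
            r = ring * tree.depth[kid]
            pos[kid] = (cx + r * math.cos(angle), cy + r * math.sin(angle))
            start += width
            stack.append(kid)
    return pos


def force_layout(tree: LayoutTree, params: LayoutParams) -> LayoutResult:
    """Iterate the modified spring embedder to (near) equilibrium.

    Bit-deterministic for fixed tree/params. All coordinates stay finite and
    inside the drawing area (clipped every iteration)."""
    nodes = sorted(tree.depth)
    if not nodes:
        return LayoutResult({}, 0, True, params)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    init = initial_positions(tree, params)
    pos = np.array([init[v] for v in nodes], dtype=float)
    rng = np.random.default_rng(params.seed % (2**31))
    pos += rng.uniform(-1.0, 1.0, size=pos.shape) * 1e-6 * params.base_edge_length

    edges = np.array(
        [[index[c], index[p]] for c, p in sorted(tree.parent.items())],
        dtype=int).reshape(-1, 2)
    targets = np.array(
        [edge_target_length(_edge_level(tree, c, p), params)
         for c, p in sorted(tree.parent.items())], dtype=float)
    adjacent = np.zeros((n, n), dtype=bool)
    if len(edges):
        adjacent[edges[:, 0], edges[:, 1]] = True
        adjacent[edges[:, 1], edges[:, 0]] = True
    np.fill_diagonal(adjacent, True)

    cutoff = params.repulsion_cutoff_fraction * min(params.area)
    k_rep = params.base_edge_length
    step_cap = 0.5 * params.base_edge_length
    dt = 0.1
    w, h = params.area

    history = [pos.copy()]
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        force = np.zeros_like(pos)
        # repulsion among non-adjacent pairs within the cutoff
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))
        mask = (~adjacent) & (dist > 1e-12) & (dist < cutoff)
        with np.errstate(divide="ignore", invalid="ignore"):
            mag = np.where(mask, k_rep * k_rep / np.maximum(dist, 1e-12) ** 2, 0.0)
        force += (diff * mag[:, :, None]).sum(axis=1)
        # springs along tree edges toward the level target length
        if len(edges):
            d = pos[edges[:, 0]] - pos[edges[:, 1]]
            length = np.sqrt((d ** 2).sum(axis=1))
            length = np.maximum(length, 1e-12)
            pull = (length - targets) / length  # >0: too long, pull together
            f = -d * pull[:, None]
            np.add.at(force, edges[:, 0], f)
            np.add.at(force, edges[:, 1], -f)
        step = force * dt
        norms = np.sqrt((step ** 2).sum(axis=1))
        too_big = norms > step_cap
        step[too_big] *= (step_cap / norms[too_big])[:, None]
        raw = history[-1] + step
        # pin the hidden root at the centre
        raw[index[tree.root]] = (w / 2.0, h / 2.0)
        history.append(raw)
        history = history[-params.damping_window:]
        new_pos = np.mean(history, axis=0)
        new_pos[:, 0] = np.clip(new_pos[:, 0], 0.0, w)
        new_pos[:, 1] = np.clip(new_pos[:, 1], 0.0, h)
        max_disp = float(np.abs(new_pos - pos).max())
        pos = new_pos
        if max_disp < params.convergence_tol:
            converged = True
            break
    positions = {v: (float(pos[i, 0]), float(pos[i, 1])) for v, i in index.items()}
    return LayoutResult(positions=positions, iterations_run=iterations,
                        converged=converged, params=params)


def write_positions_json(result: LayoutResult, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump({v: [x, y] for v, (x, y) in sorted(result.positions.items())},
                  fh, indent=0, sort_keys=True)
        fh.write("\n")
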