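"""Detection of γ-dense clusters (quasi-cliques).

A vertex set S of an undirected graph is a γ-cluster for 0 ≤ γ ≤ 1 when

    |E(S)| ≥ γ · C(|S|, 2),

i.e. its induced edge count reaches a fraction γ of the complete graph on
|S| vertices; γ = 1 recovers ordinary cliques. Finding a maximum-cardinality
γ-cluster is NP-hard, so detection uses a GRASP heuristic (greedy randomized
adaptive search procedure): a randomized greedy construction driven by the
surrogate potential

    φ(S) = |E(S)| − γ · C(|S|, 2)

(non-negative exactly when S is a γ-cluster), followed by a swap-based local
search, repeated over restarts. Candidates are restricted to vertices
adjacent to the growing set, so emitted clusters are connected — Eq.-style
density alone would happily absorb isolated vertices, which is never the
intent for network structure discovery.

:func:`max_gamma_clique_exact` is an exhaustive oracle for small graphs,
used to validate the heuristic.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Optional

import networkx as nx

from .graph_core import induced_edge_count


def _pairs(k: int) -> float:
    return k * (k - 1) / 2.0


def validate_gamma(gamma: float) -> float:
    gamma = float(gamma)
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    return gamma


@dataclass(frozen=True)
class Cluster:
    """A detected γ-cluster: member set, hierarchy level, the γ it was
    required to satisfy and the density it actually realized."""

    members: frozenset[str]
    level: int
    gamma_used: float
    density: float

    def __post_init__(self) -> None:
        validate_gamma(self.gamma_used)
        if not self.members:
            raise ValueError("cluster must have at least one member")

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class ClusterSearchParams:
    """Knobs of the GRASP search.

    gamma        required density (Eq.-style threshold).
    min_size     smallest cluster worth reporting (default 3: a single edge
                 is not structure).
    restarts     GRASP restarts; more restarts trade time for quality.
    rcl_alpha    greediness of the restricted candidate list in (0 = pure
                 greedy, 1 = uniform random); also sets the top-degree
                 fraction eligible as seed vertices.
    seed         RNG seed; identical seeds give identical clusters.
    stop_after_undersized
                 how many consecutive undersized finds end the repeated
                 extraction in :func:`create_clusters`.
    """

    gamma: float
    min_size: int = 3
    restarts: int = 20
    rcl_alpha: float = 0.2
    seed: int = 0
    stop_after_undersized: int = 1

    def __post_init__(self) -> None:
        validate_gamma(self.gamma)
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if not 0.0 <= self.rcl_alpha <= 1.0:
            raise ValueError("rcl_alpha must lie in [0, 1]")
        if self.stop_after_undersized < 1:
            raise ValueError("stop_after_undersized must be >= 1")


def gamma_density(graph: nx.Graph, members: Iterable[str]) -> float:
    """Density |E(S)| / C(|S|,2) of the induced subgraph on ``members``.

    Sets with at most one vertex have density 1.0 by convention (they can
    never fail the density test; min_size is what excludes them).
    """
    mset = set(members)
    if len(mset) <= 1:
        if mset - set(graph.nodes()):
            raise KeyError(f"nodes not in graph: {sorted(mset)}")
        return 1.0
    return induced_edge_count(graph, mset) / _pairs(len(mset))


def is_gamma_cluster(graph: nx.Graph, members: Iterable[str], gamma: float) -> bool:
    """Whether ``members`` satisfies |E(S)| ≥ γ·C(|S|,2)."""
    return gamma_density(graph, members) >= validate_gamma(gamma)


# --------------------------------------------------------------------------
# GRASP construction + local search
# --------------------------------------------------------------------------


class _State:
    """Incrementally maintained subgraph statistics for one GRASP run."""

    __slots__ = ("adj", "members", "n_edges", "deg_in")

    def __init__(self, adj: dict[str, set[str]]):
        self.adj = adj
        self.members: set[str] = set()
        self.n_edges = 0
        # deg_in[v] = edges between v and current members, for v outside S
        self.deg_in: dict[str, int] = {}

    def phi(self, gamma: float) -> float:
        return self.n_edges - gamma * _pairs(len(self.members))

    def gain(self, v: str) -> int:
        return self.deg_in.get(v, 0)

    def add(self, v: str) -> None:
        self.n_edges += self.deg_in.pop(v, 0)
        self.members.add(v)
        for u in self.adj[v]:
            if u not in self.members:
                self.deg_in[u] = self.deg_in.get(u, 0) + 1

    def remove(self, v: str) -> None:
        self.members.remove(v)
        d = 0
        for u in self.adj[v]:
            if u in self.members:
                d += 1
            elif u in self.deg_in:  # outsider loses its edge to v
                self.deg_in[u] -= 1
                if self.deg_in[u] == 0:
                    del self.deg_in[u]
        self.n_edges -= d
        if d:
            self.deg_in[v] = d

    def copy(self) -> "_State":
        s = _State(self.adj)
        s.members = set(self.members)
        s.n_edges = self.n_edges
        s.deg_in = dict(self.deg_in)
        return s


def _candidates(state: _State) -> list[str]:
    # only vertices adjacent to S: clusters stay connected
    return [v for v, d in state.deg_in.items() if d > 0]


def _greedy_fill(state: _State, gamma: float, rng: random.Random, alpha: float) -> None:
    """Add vertices while φ stays non-negative, picking each step from a
    value-based restricted candidate list over the φ gain.

    A vertex is admitted only if it individually supports the target
    density, deg_S(v) ≥ γ·|S| (which also keeps φ from decreasing).
    Without this marginal rule a large dense set slowly pads itself with
    weakly attached outsiders until the density sinks to exactly γ."""
    while True:
        cands = _candidates(state)
        if not cands:
            return
        k = len(state.members)
        # phi after adding v: phi + gain(v) - gamma*k
        gains = {v: state.gain(v) for v in cands}
        feasible = {v: g for v, g in gains.items()
                    if g >= gamma * k and state.phi(gamma) + g - gamma * k >= 0}
        if not feasible:
            return
        best = max(feasible.values())
        worst = min(feasible.values())
        cutoff = best - alpha * (best - worst)
        rcl = sorted(v for v, g in feasible.items() if g >= cutoff)
        state.add(rng.choice(rcl))


def _local_search(state: _State, gamma: float, min_size: int,
                  rng: random.Random, alpha: float) -> None:
    """Single-vertex swaps: drop a weakly connected member and re-fill
    greedily; keep the result only if the cluster grows."""
    improved = True
    while improved:
        improved = False
        members = sorted(
            state.members,
            key=lambda u: (sum(1 for w in state.adj[u] if w in state.members), u),
        )
        for u in members[: max(3, len(members) // 4)]:
            trial = state.copy()
            trial.remove(u)
            if not trial.members:
                continue
            _greedy_fill(trial, gamma, rng, alpha)
            if (len(trial.members) > len(state.members)
                    and trial.phi(gamma) >= 0
                    and len(trial.members) >= min_size):
                state.members = trial.members
                state.n_edges = trial.n_edges
                state.deg_in = trial.deg_in
                improved = True
                break


def _one_run(adj: dict[str, set[str]], seed_vertex: str, gamma: float,
             min_size: int, rng: random.Random, alpha: float) -> Optional[set[str]]:
    state = _State(adj)
    state.add(seed_vertex)
    _greedy_fill(state, gamma, rng, alpha)
    # allow growth through a short infeasible stretch while below min_size
    while len(state.members) < min_size:
        cands = _candidates(state)
        if not cands:
            break
        best = max(cands, key=lambda v: (state.gain(v), v))
        state.add(best)
    if state.phi(gamma) < 0:
        # repair: peel weakest members
        while state.members and state.phi(gamma) < 0:
            weakest = min(
                state.members,
                key=lambda u: (sum(1 for w in state.adj[u] if w in state.members), u),
            )
            state.remove(weakest)
    if not state.members:
        return None
    _greedy_fill(state, gamma, rng, alpha)
    _local_search(state, gamma, min_size, rng, alpha)
    if state.phi(gamma) < 0:
        return None
    return set(state.members)


def _cluster_key(graph: nx.Graph, members: set[str], gamma: float):
    dens = gamma_density(graph, members)
    return (-len(members), -dens, tuple(sorted(members)))


def _best_gamma_set(graph: nx.Graph, params: ClusterSearchParams) -> Optional[set[str]]:
    """Best γ-dense connected set of any size found over the restarts."""
    nodes = sorted(graph.nodes())
    if not nodes:
        return None
    gamma = params.gamma
    adj = {n: set(graph[n]) for n in nodes}
    rng = random.Random(params.seed)
    by_degree = sorted(nodes, key=lambda n: (-len(adj[n]), n))
    n_seed_pool = max(1, int(round(params.rcl_alpha * len(nodes))))
    seed_pool = by_degree[:n_seed_pool]
    best: Optional[set[str]] = None
    for _ in range(params.restarts):
        seed_vertex = rng.choice(seed_pool)
        found = _one_run(adj, seed_vertex, gamma, params.min_size, rng,
                         params.rcl_alpha)
        if found is None:
            continue
        if best is None or _cluster_key(graph, found, gamma) < _cluster_key(
                graph, best, gamma):
            best = found
    return best


def construct_dsubg(graph: nx.Graph, params: ClusterSearchParams) -> Optional[Cluster]:
    """One-cluster GRASP search: the largest γ-cluster of size ≥ min_size
    found over the restarts (ties: higher density, then lexicographically
    smallest member set), or None. Deterministic for a fixed seed."""
    best = _best_gamma_set(graph, params)
    if best is None or len(best) < params.min_size:
        return None
    level = max((graph.nodes[n].get("level", 0) for n in best), default=0) + 1
    return Cluster(
        members=frozenset(best),
        level=level,
        gamma_used=params.gamma,
        density=gamma_density(graph, best),
    )


def create_clusters(graph: nx.Graph, params: ClusterSearchParams) -> list[Cluster]:
    """Repeatedly extract vertex-disjoint γ-clusters from one level.

    After each cluster is found its members leave the candidate pool;
    extraction stops when the search comes up empty or has produced
    ``stop_after_undersized`` clusters below min_size (which are not
    emitted). Because clusters are vertex-disjoint, densities are identical
    in the shrinking pool and in the original level graph; they are
    recomputed against the original graph regardless.
    """
    pool = set(graph.nodes())
    out: list[Cluster] = []
    undersized = 0
    round_no = 0
    while pool:
        sub = graph.subgraph(pool)
        p = replace(params, seed=(params.seed + 0x9E37 * round_no) % (2**31))
        round_no += 1
        found = _best_gamma_set(sub, p)
        if found is None:
            break
        if len(found) < params.min_size:
            undersized += 1
            if undersized >= params.stop_after_undersized:
                break
            pool -= found
            continue
        level = max((graph.nodes[n].get("level", 0) for n in found), default=0) + 1
        out.append(
            Cluster(
                members=frozenset(found),
                level=level,
                gamma_used=params.gamma,
                density=gamma_density(graph, found),
            )
        )
        pool -= found
    return out


# --------------------------------------------------------------------------
# Exhaustive oracle
# --------------------------------------------------------------------------

_EXACT_NODE_LIMIT = 20


def max_gamma_clique_exact(graph: nx.Graph, gamma: float) -> set[str]:
    """Exhaustively find a maximum-cardinality γ-cluster (ties broken
    lexicographically). Exponential — guarded to ≤ 20 nodes; intended as a
    validation oracle for the GRASP heuristic."""
    gamma = validate_gamma(gamma)
    nodes = sorted(graph.nodes())
    n = len(nodes)
    if n > _EXACT_NODE_LIMIT:
        raise ValueError(
            f"exact search limited to {_EXACT_NODE_LIMIT} nodes, got {n}")
    if n == 0:
        return set()
    index = {v: i for i, v in enumerate(nodes)}
    masks = [0] * n
    for u, v in graph.edges():
        masks[index[u]] |= 1 << index[v]
        masks[index[v]] |= 1 << index[u]
    for size in range(n, 1, -1):
        need = gamma * _pairs(size)
        for combo in combinations(range(n), size):
            mask = 0
            for i in combo:
                mask |= 1 << i
            edges = sum((masks[i] & mask).bit_count() for i in combo) // 2
            if edges >= need:
                return {nodes[i] for i in combo}
    return {nodes[0]}  # singletons have density 1.0 by convention


def write_clusters_tsv(clusters: Iterable[Cluster], path) -> None:
    """One row per member: cluster_id, level, gamma, density, member."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tlevel\tgamma\tdensity\tmember\n")
        for i, c in enumerate(clusters):
            for m in c.sorted_members():
                fh.write(f"C{c.level}_{i}\t{c.level}\t{c.gamma_used:g}\t"
                         f"{c.density:.6f}\t{m}\n")
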