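"""Seeded synthetic generators for the structures dense biological networks
exhibit: tight clusters embedded in a sparse background (planted
partitions), cliques bridged by matchings (the configuration that defeats
minimum-spanning-tree layouts), skewed scale-free degree distributions, and
block-structured expression matrices driving co-expression networks.

Every generator is a pure function of its parameters and seed; conventions
(attachment start, matching order, node naming) are fixed so edge counts in
downstream tests are stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from . import graph_core as gcore

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlantedPartitionSpec:
    """Blocks of ``block_size`` nodes; edge probability ``p_in`` within a
    block and ``p_out`` between blocks."""

    n_blocks: int
    block_size: int
    p_in: float
    p_out: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.block_size < 2:
            raise ValueError("need n_blocks >= 1 and block_size >= 2")
        for p in (self.p_in, self.p_out):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_in <= self.p_out:
            logger.warning(
                "p_in (%.3f) <= p_out (%.3f): planted structure will not be "
                "denser than the background", self.p_in, self.p_out)


def planted_partition(spec: PlantedPartitionSpec) -> tuple[nx.Graph, dict[str, int]]:
    """Bernoulli planted-partition graph plus its ground-truth block map."""
    rng = np.random.default_rng(spec.seed % (2**31))
    names = [f"b{b}n{i:02d}" for b in range(spec.n_blocks)
             for i in range(spec.block_size)]
    block = {name: int(name[1:name.index("n")]) for name in names}
    graph = gcore.new_graph()
    for name in names:
        gcore.add_base_node(graph, name)
    for u, v in combinations(names, 2):
        p = spec.p_in if block[u] == block[v] else spec.p_out
        if rng.random() < p:
            gcore.add_base_edge(graph, u, v)
    return graph, block


def cliques_joined_by_matching(clique_size: int, n_cliques: int = 2,
                               seed: int = 0) -> nx.Graph:
    """Disjoint cliques of equal size, consecutive pairs joined by a perfect
    matching (node i of clique k to node i of clique k+1). Deterministic —
    the seed is accepted for interface uniformity only."""
    if clique_size < 3:
        raise ValueError("clique_size must be >= 3")
    if n_cliques < 1:
        raise ValueError("n_cliques must be >= 1")
    graph = gcore.new_graph()
    for k in range(n_cliques):
        names = [f"q{k}n{i:02d}" for i in range(clique_size)]
        for u, v in combinations(names, 2):
            gcore.add_base_edge(graph, u, v)
    for k in range(n_cliques - 1):
        for i in range(clique_size):
            gcore.add_base_edge(graph, f"q{k}n{i:02d}", f"q{k + 1}n{i:02d}")
    return graph


def scale_free_graph(n: int, m: int, seed: int = 0) -> nx.Graph:
    """Barabási–Albert preferential attachment: m initial unconnected
    nodes, each subsequent node attaches to m existing nodes, giving
    exactly (n − m)·m edges."""
    if not 1 <= m < n:
        raise ValueError("need 1 <= m < n")
    raw = nx.barabasi_albert_graph(n, m, seed=seed % (2**31))
    graph = gcore.new_graph()
    for node in raw.nodes():
        gcore.add_base_node(graph, f"v{node:04d}")
    for u, v in raw.edges():
        gcore.add_base_edge(graph, f"v{u:04d}", f"v{v:04d}")
    return graph


def random_graph(n: int, p: float, seed: int = 0) -> nx.Graph:
    """Erdős–Rényi G(n, p) with the package's node conventions; the sparse
    null model the other generators are compared against."""
    raw = nx.gnp_random_graph(n, p, seed=seed % (2**31))
    graph = gcore.new_graph()
    for node in raw.nodes():
        gcore.add_base_node(graph, f"v{node:04d}")
    for u, v in raw.edges():
        gcore.add_base_edge(graph, f"v{u:04d}", f"v{v:04d}")
    return graph


def synthetic_expression(
    n_blocks: int,
    genes_per_block: int,
    n_samples: int,
    noise_sd: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Block-structured expression matrix: each block of genes follows one
    standard-normal latent factor plus independent Gaussian noise, so the
    expected within-block correlation is 1/(1 + noise_sd²) and between-block
    correlations are null. Returns the matrix (genes × samples) and the
    ground-truth block map."""
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed % (2**31))
    factors = rng.standard_normal((n_blocks, n_samples))
    genes, rows, block = [], [], {}
    for b in range(n_blocks):
        for j in range(genes_per_block):
            name = f"g{b}_{j:03d}"
            genes.append(name)
            block[name] = b
            rows.append(factors[b] + noise_sd * rng.standard_normal(n_samples))
    matrix = pd.DataFrame(np.array(rows), index=genes,
                          columns=[f"s{j:03d}" for j in range(n_samples)])
    return matrix, block


def write_ground_truth_tsv(mapping: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tblock\n")
        for name in sorted(mapping):
            fh.write(f"{name}\t{mapping[name]}\n")
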