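"""Gene co-expression network construction.

Given an expression matrix (genes × samples), the all-pairs Pearson
correlation matrix is computed and an edge introduced between two genes
whenever their correlation exceeds a threshold (strictly, by default —
"above" — configurable to ≥). Typical thresholds for genome-wide arrays sit
around 0.7–0.8; lowering the threshold grows the edge set monotonically,
which :func:`edge_count_monotonicity` exposes as a property-test helper.

Genes with zero expression variance have undefined correlations; they are
excluded pairwise (and logged). Genes left without any edge are dropped by
default so the network contains only connected genes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from . import graph_core as gcore

logger = logging.getLogger(__name__)


def validate_threshold(threshold: float) -> float:
    threshold = float(threshold)
    if not -1.0 < threshold < 1.0:
        raise ValueError(f"correlation threshold must lie in (-1, 1), got {threshold}")
    return threshold


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """TSV with gene identifiers in the first column and one column per
    sample (header row of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _validate_matrix(df)
    return df


def _validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.shape[1] < 3:
        raise ValueError(
            f"need at least 3 samples to correlate, got {matrix.shape[1]}")
    if matrix.shape[0] < 2:
        raise ValueError(f"need at least 2 genes, got {matrix.shape[0]}")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite entries")


def correlation_network(
    matrix: pd.DataFrame,
    threshold: float,
    *,
    strict: bool = True,
    use_abs: bool = False,
    drop_isolated: bool = True,
) -> nx.Graph:
    """Threshold the Pearson correlation matrix into an undirected graph.

    ``strict`` uses r > t (default, edges require correlation strictly
    above the threshold); ``use_abs`` correlates on |r| instead of signed r
    (off by default — anti-correlated genes give no edge).
    """
    _validate_matrix(matrix)
    threshold = validate_threshold(threshold)
    values = matrix.to_numpy(dtype=float)
    genes = [str(g) for g in matrix.index]
    variances = values.var(axis=1)
    usable = variances > 0
    n_constant = int((~usable).sum())
    if n_constant:
        logger.warning("%d gene(s) with zero variance excluded from correlation",
                       n_constant)
    graph = gcore.new_graph()
    if usable.sum() >= 2:
        corr = np.corrcoef(values[usable])
        score = np.abs(corr) if use_abs else corr
        rows = np.array(genes, dtype=object)[usable]
        ii, jj = np.triu_indices(len(rows), k=1)
        keep = score[ii, jj] > threshold if strict else score[ii, jj] >= threshold
        for i, j in zip(ii[keep], jj[keep]):
            gcore.add_base_edge(graph, rows[i], rows[j])
    if not drop_isolated:
        for g in genes:
            if g not in graph:
                gcore.add_base_node(graph, g)
    return graph


def edge_count_monotonicity(matrix: pd.DataFrame, t1: float, t2: float) -> bool:
    """Whether the network at the lower threshold t1 has at least as many
    edges as at t2 (> t1). Always true — thresholding is monotone; exposed
    for property tests."""
    if not t1 < t2:
        raise ValueError("expected t1 < t2")
    g1 = correlation_network(matrix, t1)
    g2 = correlation_network(matrix, t2)
    return g1.number_of_edges() >= g2.number_of_edges()
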