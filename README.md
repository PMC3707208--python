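# gammanet

Structural visualization of large, dense biological networks — metabolic
reaction networks, gene co-expression networks, protein interaction maps —
whose sheer edge count defeats ordinary graph drawing. Instead of trying to
place every edge, `gammanet` first *analyzes* the graph, replaces its dense
substructures with semantic symbols, and draws only a skeleton that carries
the global structure; the hidden edges stay one query away.

## The method

A **γ-cluster** (quasi-clique) of an undirected graph G = (V, E) is a
vertex set S ⊆ V whose induced subgraph reaches a fraction γ of all
possible edges:

    |E(S)| ≥ γ · C(|S|, 2),        0 ≤ γ ≤ 1,

so γ = 1 is an ordinary clique. Maximum-cardinality γ-cluster search is
NP-hard; `gammanet` uses a GRASP heuristic (randomized greedy construction
on the potential φ(S) = |E(S)| − γ·C(|S|,2), plus swap-based local search,
over restarts) and validates it against an exhaustive oracle on small
graphs. The pipeline then proceeds in three steps:

1. **Multilevel γ-clustering** — disjoint γ-clusters are extracted,
   replaced by cluster nodes (with membership edges to their members and
   intercluster edges wherever any lower-level edge connects two clusters),
   and the process recurses on the cluster nodes with a per-level γᵢ
   (default schedule 0.5, then 0.7 — the working graph densifies as levels
   rise, so γ grows).
2. **Tree transformation** — a hidden root adopts the top-level clusters;
   breadth-first search keeps only shortest-path edges, members hang under
   their own cluster node, and all other edges are hidden.
3. **Hierarchy-aware force-directed layout** — concentric-circle
   initialization around the root, level-dependent target edge lengths
   (longer on higher levels), a repulsion cutoff proportional to the
   drawing area, and position-averaging damping.

Two drill-down queries recover what the picture hides: the edges incident
to any node or cluster, and the internal edges a cluster symbol replaces.
Together they reconstruct the original edge set exactly — the drawing loses
no information, it just defers it.

## Worked example

Two 8-cliques joined by a perfect matching are exactly the configuration
that collapses into an unreadable star under spanning-tree-based layouts:

```python
from gammanet import ClusterSearchParams, create_clusters, cliques_joined_by_matching

graph = cliques_joined_by_matching(clique_size=8, n_cliques=2)
clusters = create_clusters(graph, ClusterSearchParams(
    gamma=1.0, min_size=3, restarts=20, seed=0))
for i, c in enumerate(clusters):
    print(f"cluster {i}: size={c.size} density={c.density:.2f}")
```

prints

```
cluster 0: size=8 density=1.00
cluster 1: size=8 density=1.00
```

— the two cliques, recovered exactly, with the matching edges left between
the resulting cluster nodes. Running the multilevel hierarchy on two K4s
bridged by one edge (`examples/02_multilevel_hierarchy.py`) yields two
level-1 clusters, one level-2 cluster over them, and a 12-node spanning
tree with the original nodes at depth 3:

```
levels built: 2
  level 0: 8 nodes, 13 edges
  level 1: 2 nodes, 1 edges
  level 2: 1 nodes, 0 edges
tree: 12 nodes (incl. hidden root), 11 edges
```

The `examples/` directory holds one short script per capability: cluster
detection, hierarchy + tree, layout + SVG rendering with drill-down
highlights, co-expression network construction from an expression matrix,
and the full deterministic pipeline. The same steps are available from the
shell:

```sh
gammanet simulate planted --seed 3 -o net.tsv
gammanet run net.tsv --gamma-schedule 0.5,0.7 --seed 1 -o out/
```

which writes `clusters.tsv`, `hierarchy.graphml`, `tree.graphml`,
`positions.json`, `network.svg` and a `manifest.json` that fully determines
the run.

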