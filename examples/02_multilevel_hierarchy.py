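"""Build the multilevel hierarchy and its layout tree for two K4s joined by
a single edge.

Level 1 finds the two dense blocks at γ=0.5; level 2 merges their cluster
nodes (joined by one witnessed intercluster edge) at γ=0.7 into a single
top cluster, and the tree transformation roots everything under a hidden
root: top cluster at depth 1, block clusters at depth 2, original nodes at
depth 3.
"""

from gammanet import (ClusterSearchParams, GammaSchedule,
                      create_multilevel_clusters, level_subgraph,
                      tree_transformation)
from gammanet.graph_core import add_base_edge, new_graph

graph = new_graph()
for block in ("a", "b"):
    for i in range(4):
        for j in range(i + 1, 4):
            add_base_edge(graph, f"{block}{i}", f"{block}{j}")
add_base_edge(graph, "a0", "b0")

hierarchy = create_multilevel_clusters(
    graph, GammaSchedule((0.5, 0.7)),
    ClusterSearchParams(gamma=0.5, min_size=2, restarts=20, seed=11))

print(f"levels built: {hierarchy.n_levels}")
for level in range(hierarchy.n_levels + 1):
    sub = level_subgraph(hierarchy, level)
    print(f"  level {level}: {sub.number_of_nodes()} nodes, "
          f"{sub.number_of_edges()} edges")

tree = tree_transformation(hierarchy, seed=0)
print(f"tree: {len(tree.depth)} nodes (incl. hidden root), "
      f"{len(tree.tree_edges())} edges")
for node in sorted(tree.depth, key=lambda n: (tree.depth[n], n)):
    print(f"  depth {tree.depth[node]}: {node}")
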