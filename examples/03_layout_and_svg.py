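"""Lay out and render a planted-partition network.

Three dense 10-node blocks in a sparse background become three level-1
cluster nodes; the drawing shows each block as a star around its cluster
symbol, with higher-level edges drawn longer than the membership spokes.
The drill-down queries recover the edges the picture hides.
"""

from gammanet import (ClusterSearchParams, GammaSchedule, LayoutParams,
                      PlantedPartitionSpec, cluster_internal_edges,
                      create_multilevel_clusters, force_layout, hidden_edges,
                      highlight_neighbors, planted_partition, render_svg,
                      tree_transformation)

graph, blocks = planted_partition(PlantedPartitionSpec(
    n_blocks=3, block_size=10, p_in=0.9, p_out=0.02, seed=0))
hierarchy = create_multilevel_clusters(
    graph, GammaSchedule((0.5, 0.7)),
    ClusterSearchParams(gamma=0.5, min_size=3, restarts=20, seed=0))
tree = tree_transformation(hierarchy, seed=0)
layout = force_layout(tree, LayoutParams(seed=0))

shown = tree.tree_edges() & {frozenset(e) for e in hierarchy.graph.edges()}
print(f"hierarchy edges: {hierarchy.graph.number_of_edges()}, "
      f"drawn in default view: {len(shown)}, hidden: {len(hidden_edges(tree))}")

cluster_node = hierarchy.cluster_nodes(1)[0]
internal = cluster_internal_edges(tree, cluster_node)
incident = highlight_neighbors(tree, cluster_node)
print(f"drill-down on {cluster_node}: {len(internal)} internal edges, "
      f"{len(incident)} incident connections")

render_svg(tree, layout, "planted.svg", highlights=internal)
print("wrote planted.svg with the first cluster's internal edges highlighted")
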