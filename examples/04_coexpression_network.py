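"""Threshold a gene expression matrix into a co-expression network.

Two blocks of genes each follow their own latent factor; Pearson
correlation above the threshold defines the edges. A lower threshold always
yields a superset of the edges of a higher one, so the network thins out —
but the block structure persists — as the threshold rises.
"""

from gammanet import correlation_network, synthetic_expression

matrix, blocks = synthetic_expression(
    n_blocks=2, genes_per_block=15, n_samples=60, noise_sd=0.55, seed=3)
print(f"matrix: {matrix.shape[0]} genes x {matrix.shape[1]} samples")

for threshold in (0.72, 0.80):
    net = correlation_network(matrix, threshold)
    within = sum(blocks[u] == blocks[v] for u, v in net.edges())
    print(f"threshold {threshold:.2f}: {net.number_of_nodes()} genes, "
          f"{net.number_of_edges()} edges "
          f"({within} within-block, {net.number_of_edges() - within} between)")
print("Edges at 0.80 are a subset of edges at 0.72; nearly all sit within "
      "the planted co-expression blocks.")
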