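# Methods

## Model

`gammanet` treats a biological network as a simple undirected graph
G = (V, E). A vertex set S is a **γ-cluster** when |E(S)| ≥ γ·C(|S|,2);
density is defined as |E(S)| / C(|S|,2), with the convention that sets of
at most one vertex have density 1.0 (they can never fail the test — the
`min_size` parameter, default 3, is what excludes trivia). The package's
goal is structural: find large, disjoint, *connected* γ-clusters, stack
them into a hierarchy, and draw the hierarchy instead of the raw graph.

## Cluster search (GRASP)

Maximum-cardinality γ-cluster search is NP-hard, so detection is heuristic:

* **Surrogate potential.** φ(S) = |E(S)| − γ·C(|S|,2), non-negative exactly
  when S is a γ-cluster. All greedy decisions are ranked by the φ gain of a
  candidate vertex, which is simply its edge count into S.
* **Construction.** Each restart seeds from a vertex drawn among the top
  `rcl_alpha` fraction (default 0.2) of vertices by degree, then grows S
  one vertex at a time. Candidates are restricted to neighbours of S —
  clusters are connected by construction; pure density would happily absorb
  isolated vertices. Each addition step draws uniformly from a value-based
  restricted candidate list (all candidates within `rcl_alpha` of the best
  gain), which keeps restarts diverse; a purely greedy step after a
  randomized seed would collapse the restarts onto a handful of distinct
  trajectories.
* **Marginal-degree acceptance.** A vertex joins only if deg_S(v) ≥ γ·|S|,
  i.e. it individually supports the target density (this also keeps φ
  non-decreasing, hence non-negative). The weaker rule "accept while
  φ ≥ 0" lets a large dense set pad itself with weakly attached outsiders
  until its density sinks to exactly γ; with the marginal rule a planted
  10-node block at p_in = 0.9 is recovered essentially exactly rather than
  with one or two hangers-on.
* **Local search.** Repeatedly drop a weakest member and greedily re-fill;
  keep the swap only if the cluster grows. Below `min_size` the search may
  grow through a short infeasible stretch and repair by peeling weakest
  members.
* **Selection.** Best over `restarts` runs: largest member set, ties broken
  by higher density, then by lexicographically smallest member tuple —
  making results total-order deterministic under a fixed seed.

`max_gamma_clique_exact` enumerates all vertex subsets (guarded to ≤ 20
nodes, bitmask edge counting) and is the oracle the heuristic is tested
against: on 100 random graphs with 5–12 nodes at γ = 1 the GRASP search
ties the exact maximum in ≈100% of trials and can never exceed it.

Repeated extraction removes each found cluster's members from the candidate
pool, so clusters on one level are vertex-disjoint; extraction stops when
the search comes up empty or the best find drops below `min_size` (the
number of undersized finds tolerated is configurable, default 1). Because
clusters are disjoint, densities computed in the shrinking pool equal those
in the original level graph.

## Hierarchy

Levels are built bottom-up. Level i clusters the graph whose nodes are the
level-(i−1) cluster nodes and whose edges are the intercluster edges
witnessed one level below. Per-level γᵢ comes from a schedule (default 0.5,
then 0.7 repeating); the working graph densifies as levels rise, so a
non-decreasing schedule is recommended and a decreasing one only warns.
Construction stops when a level yields no clusters or a single cluster.
Nodes left unclustered at some level do not participate in higher levels —
clustering proceeds "among the clusters" — but keep their original edges,
which the tree phase uses to reach them.

## Tree transformation

A hidden root adopts every top-level cluster node. BFS over the full
hierarchy graph (base + intercluster + membership edges) assigns depths;
each node's parent is a neighbour one step closer to the root, preferring
the node's own cluster when that cluster is depth-minimal (it virtually
always is; the preference is applied conditionally so that depths always
equal BFS distances), with residual ties broken by one seeded generator.
Components containing no cluster anywhere are unreachable; each attaches to
the root by one synthetic edge at its smallest node and is flagged as an
orphan. Tree edges and hidden edges partition the hierarchy's edge set.

## Layout

Spring embedder over the tree only:

* spring force proportional to (distance − target) along tree edges, where
  target = `base_edge_length` × `level_factor`^level (defaults 30 and 1.8;
  the edge level is the lower endpoint's hierarchy level, root edges take
  the top level) — higher levels draw longer;
* Fruchterman–Reingold-style repulsion k²/d (k = `base_edge_length`)
  between non-adjacent pairs within a cutoff of
  `repulsion_cutoff_fraction` × min(area) (default 0.25). Excluding
  adjacent pairs lets an isolated edge equilibrate exactly at its target
  length; the cutoff keeps disconnected pieces from drifting apart;
* initialization on concentric circles (ring spacing 0.45·min(area)/height)
  with nested angular segments sized by subtree leaf counts, plus a seeded
  jitter of 10⁻⁶·`base_edge_length` to break exact symmetry;
* damping: each node's position is the mean of its last `damping_window`
  (default 3) raw updates; per-step displacement is capped at half the base
  edge length; positions are clipped to the drawing area every iteration,
  so no coordinate can become non-finite;
* termination when the maximum per-node displacement falls below
  `convergence_tol` (default 0.5 units) or after `max_iterations` (default
  300); the `converged` flag reports which.

The whole simulation is vectorized and bit-deterministic for a fixed seed.

## Rendering and drill-down

The default view draws tree edges only; base nodes are dots coloured by
quantile-binned original-graph degree (5 bins), cluster nodes are squares
whose size grows strictly with level, the root and its synthetic edges are
never drawn. SVG is serialized with fixed two-decimal formatting, so equal
scenes give byte-equal files. `highlight_neighbors` returns a node's
original edges (for a cluster: all incident hierarchy edges plus the
member-to-outside edges); `cluster_internal_edges` returns the level-below
edges among a cluster's members. The union of all clusters' internal edges
with the edges interior to no cluster reconstructs the original edge set
exactly.

## Co-expression networks

`correlation_network` thresholds the all-pairs Pearson correlation of a
genes × samples matrix: an edge requires r strictly above the threshold
(configurable to ≥; absolute-value correlation is off by default, so
anti-correlated genes give no edge). Zero-variance genes are excluded
pairwise; isolated genes are dropped by default. Edge sets nest as the
threshold rises — the monotonicity helper exposes this as a testable
property.

## Synthetic data

The generators emulate the structures the pipeline targets, at desk scale:

* `planted_partition` — Bernoulli blocks (defaults used in tests: 3 blocks
  × 10 nodes, p_in = 0.9, p_out = 0.02), the ground truth for recovery
  tests;
* `cliques_joined_by_matching` — the configuration that folds into a
  misleading star under minimum-spanning-tree preprocessing;
* `scale_free_graph` — Barabási–Albert attachment with exactly (n−m)·m
  edges, for the skewed degree distributions of biological networks;
* `synthetic_expression` — one latent factor per gene block plus Gaussian
  noise, giving expected within-block correlation 1/(1 + σ²) and null
  between-block correlation.

All generators are pure functions of parameters + seed. What they do *not*
model: overlapping modules, hub-and-spoke cluster structure inside blocks,
heteroscedastic or non-Gaussian expression noise, batch effects, and the
size of real genome-wide networks (tests run at tens-to-hundreds of nodes,
chosen so the full suite completes in minutes). Passing tests therefore
demonstrate correctness of the machinery and recovery under clean planted
structure, not performance claims on real proprietary datasets.

## Numerical and design choices

* Density of singletons is 1.0; `min_size` does the excluding.
* Cluster identifiers are generated as `C<level>_<index>`, prefix-escaped
  with underscores until they collide with no input identifier.
* Undersized-stop count for repeated extraction defaults to 1.
* Weights in input files are ignored (all edges are treated uniformly);
  duplicate and self-loop lines are dropped with logged counts.
* The pathological matched-cliques fixture is clustered at γ = 1.0: by
  direct computation the two cliques are the optimal clusters only for
  γ > 29/36 (a clique plus one matched neighbour is denser-than-γ below
  that), so clique-level density is the setting in which that structure is
  the right answer.
* The run manifest contains parameters, seed and per-level summaries but no
  timings or timestamps, so identical configs produce byte-identical
  manifests; stage timings go to logging.

## Known limitations

Cluster search is heuristic — no optimality guarantee beyond the oracle
parity measured on small graphs. Clusters are disjoint by design;
overlapping modules are split arbitrarily between competitors. The layout
is O(n²) per iteration and intended for the reduced tree (thousands of
nodes), not the raw network. GraphML reading supports the package's own
attribute schema plus plain graphs; exotic GraphML features (ports,
hyperedges, nested graphs) are out of scope.
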