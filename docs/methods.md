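# Methods

## The model

A subject's resting-state brain is represented as an undirected weighted
graph: nodes are the 94 regions of a cortical atlas, edge weights are
functional-connectivity correlations in [-1, 1]. Only the non-negative part
F+ is analysed. Thresholding F+ at t (edge iff weight >= t; at t = 0 a
strictly positive weight is required, so zeroed negatives never become
edges) yields a binary graph per subject.

### Graphlets and orbits

A graphlet is a small connected induced subgraph; on 2-5 nodes there are
exactly 30 of them, with 73 automorphism-orbit classes under the standard
numbering (orbit 0 = edge endpoint = degree; orbits 1/2 = path endpoint /
midpoint; ... orbit 72 = 5-clique member). The catalog is generated from
scratch (enumerate all labelled graphs, deduplicate by the minimum over node
permutations of an adjacency bit-encoding, recompute orbit partitions by
exhaustive permutation search) and cross-checked against a hardcoded
transcription of the published numbering; any mismatch aborts loudly.
Because orbit counts obey linear identities (e.g. triangles at a node =
C(degree, 2) - path-midpoints), only 56 of the 73 orbits are informative;
downstream analysis uses that fixed list.

The per-node graphlet degree vector (GDV) counts how often a node touches
each orbit. Counting enumerates every connected induced subgraph on 2-5
nodes exactly once (ESU: grow from the lowest-index root, extend only with
higher-index exclusive neighbours) and classifies it through a precomputed
labelled-graph lookup, which makes the cost proportional to the number of
such subgraphs. That number explodes on dense graphs - a 94-node graph with
six hub nodes and 16% background density takes ~1 minute in this
implementation - so a configurable `max_subgraphs` guard aborts pathological
inputs instead of stalling. A brute-force subset enumerator (<= 15 nodes)
serves as an independent oracle in the tests.

### Frequency tables and the column-equivalence scan

Per subject, the GDV is binarized (does node i touch orbit j at all?) and
restricted to the 56 informative orbits; summing over subjects gives the
frequency table (entries in [0, S]). Each column is sorted non-increasingly,
ties broken by ascending node label, with node provenance recorded. For
steps k = 1..r (r = top quartile of nodes, 24 for the 94-node atlas) two
columns are *equivalent* when their top r - k + 1 node sets coincide as
sets; the output table entry (j, k) counts the columns equivalent to j,
excluding j itself. The earliest step with any equivalence, and the node
sets shared there, define the topologically dominant nodes; intersecting
those sets across thresholds gives the persistent set.

Two semantic choices the source material leaves open:

* **Tie handling.** A top-d window that straddles a frequency tie is an
  artifact of the arbitrary tie-break, and a window containing zeros carries
  no evidence. Under the default `tie_policy="exclude"` such columns simply
  do not participate at that depth; `tie_policy="label"` keeps the plain
  label-ordered behaviour. On well-spread real tables the policies agree;
  on degenerate cohorts (many all-zero or saturated columns) the default
  prevents large spurious groups.
* **Persistence.** Set equality at depth d does not mathematically imply
  equality at d-1, so the strict per-step relation is the default; a
  `cumulative` flag provides the monotone closure (once equivalent, always
  equivalent at later steps).

### Network comparison

Each subject's 94 x 56 orbit-count matrix is summarized by its graphlet
correlation matrix (GCM): pairwise Spearman correlations between orbit
columns (rank correlation, because counts span scales; raw counts by
default, binary touch indicators behind a flag; correlations with constant
columns are set to 0 with a warning). The graphlet correlation distance
(GCD) between two subjects is the Euclidean distance between the strict
upper triangles (1540 coordinates), hence an exact Euclidean metric.
Clustering uses Ward's criterion via the Lance-Williams recurrence on the
GCD (scipy's implementation; deterministic given the matrix), cut at two
clusters by default. Validation: silhouettes s_i = (b_i - a_i)/max(a_i, b_i)
computed on the raw GCD distances (singletons get 0); attribute association
via an exact binomial test (two-sided by doubling the smaller tail, capped
at 1, against the whole-sample proportion) and a permutation test
(statistic = absolute between-cluster difference in attribute proportion,
seeded permutations, add-one p-value, so p >= 1/(n_perm + 1)).

### Null model

Degree-preserving randomization (DPR) applies double-edge swaps to the
thresholded graph: 10 x |E| successful swaps by default (the common mixing
heuristic; the source analysis states no count), with a 100 x |E| attempt
guard; graphs with no legal swap (triangle, 2-edge path) return unchanged.
Cohorts derive per-subject seeds as base + index.

## Synthetic cohorts

The generator draws, per subject, a symmetric matrix with iid Gaussian
upper-triangle entries clipped to [0, 1]: core-incident pairs (a planted
set of 6 labels by default) around mean 0.6, everything else around
0.05 + the subject population's density shift, noise sd 0.05, zero
diagonal. Default dimensions are 94 nodes x 133 subjects; two equal
populations with shifts 0 and 0.15 carry a sex-like binary attribute and a
uniform age 6-79. Weights are not proper correlation matrices
(positive-definiteness is irrelevant downstream) and no spatial or temporal
structure of fMRI is emulated, so passing tests demonstrate algorithmic
correctness and recoverability of planted structure, not neuroscientific
validity.

What the construction does and does not support:

* With noise 0 and a threshold between background and core weight, every
  subject's graph is exactly the clique on the core plus its spokes; the
  scan recovers the core exactly (the core columns are the only ones that
  participate, at depth = |core|).
* With noise, recovery is assessed at t = background + 3 sd (0.2). At more
  permissive thresholds the spurious background cycles dominate: a core
  node adjacent to *every* node cannot lie on an induced 4-cycle (it has no
  non-neighbours), and cycle-completion orbit pairs (the 4-cycle orbit and
  the wheel-rim orbit, whose touch indicators coincide exactly when the
  core is universal) tie at every depth. The earliest equivalence is then
  an honest statement about background structure, not about the core. This
  is a real limitation of binarized-touch analysis at low thresholds.
* The planted structure is degree-determined: the core is high-weight to
  all nodes, and a universal node admits no double-edge swap, so the DPR
  twin of a synthetic cohort is statistically the structured cohort with
  only its background reshuffled. Earliest-equivalence steps consequently
  tie between structured cohorts and their DPR twins (10/10 replicates in
  the packaged experiment); the twins are never *earlier*, but the strict
  "randomization delays equivalence" contrast seen on real data is not
  reproducible with this generator. Reproducing it would require planting
  structure invisible to the degree sequence (e.g. modular or
  geometric organisation).

## Numerical and design notes

* Node labels are 1-based atlas ids externally, 0-based indices internally;
  the boundary is crossed only in I/O.
* Matrices are accepted as symmetric within 1e-9; asymmetry up to 1e-6 is
  averaged away with a warning; beyond that is an error.
* Written tables round-trip exactly for integers and to 12 significant
  digits for reals (`%.12g`).
* Sorting ties, merge ties and permutation draws are all deterministic
  given the configured seeds; cluster labels are renumbered in order of
  first appearance.
* The row budget generalizes as r = ceil(n/4) for non-94-node atlases.
* t-SNE embedding of the GCD matrix is deliberately not provided; it adds
  no correctness-relevant information to the dendrogram/silhouette outputs.

## Problem sizes used in the packaged tests

Catalog and counter checks run on all 30 graphlets and on 108 random graphs
(<= 10 nodes, densities 0.1-0.9) against the brute-force oracle.
Planted-core experiments use 30-node, 6-8-subject cohorts (noiseless
recovery at t in {0.1, 0.2}; noisy recovery, 10 seeds, at t = 0.2); cluster
recovery uses 24 nodes and 80 subjects (40 + 40); the GCD metric suite uses
20 subjects at 16 nodes. These are scaled-down instances of the default
94 x 133 construction chosen to keep the exhaustive subgraph enumeration
fast; the constructions themselves are identical.
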