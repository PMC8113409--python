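# gdvnet

Graphlet-based topological analysis of resting-state functional brain
networks.

Resting-state fMRI yields, per subject, a symmetric matrix of
functional-connectivity correlations between atlas regions. `gdvnet`
implements a graphlet pipeline over cohorts of such matrices, for
researchers who want a *topological* (rather than purely statistical)
characterization of the dominant regions at rest:

1. **Orbit counting.** Threshold each subject's positive correlations into
   a binary graph and compute every node's *graphlet degree vector* (GDV):
   the number of times the node touches each of the 73 automorphism orbits
   O0-O72 of the 30 connected graphs G0-G29 on 2-5 nodes (O0 = degree,
   O1/O2 = path end/middle, ...). Only 56 orbits are linearly independent;
   the pipeline restricts to that list.
2. **Topologically relevant nodes.** Binarize GDVs (touch/no-touch), sum
   over the cohort into a frequency table M_f = Σ_h M_h⁺, sort each orbit
   column, and scan all column pairs for *set equivalence* of their top
   r−k+1 entries at steps k = 1..r (r = top quartile of nodes). Orbit
   columns that keep sharing one small node set expose the cohort's
   topologically dominant regions — on real resting-state data these are
   default-mode-network hubs.
3. **Network comparison.** Summarize each subject by the 56×56 Spearman
   *graphlet correlation matrix* (GCM); compare subjects by the Euclidean
   distance of GCM upper triangles (GCD); cluster with Ward's method;
   validate with silhouettes s_i = (b_i−a_i)/max(a_i,b_i) and
   binomial/permutation attribute tests.
4. **Null model.** Degree-preserving randomization (double-edge swaps) of
   the thresholded cohort.
5. **Synthetic cohorts.** A generator that plants a high-connectivity core
   and attribute-linked subpopulations, so the whole pipeline is testable
   without any data download.

See `docs/methods.md` for the model, parameter defaults, numerical
conventions and known limitations.

## Worked example

Simulate a 30-node, 8-subject cohort with a planted 6-node core, extract
the relevant nodes, and compare the subjects (two density-shifted
subpopulations are planted by default):

```sh
$ gdvnet simulate --n-nodes 30 --n-subjects 8 --seed 1 --outdir cohort
wrote cohort manifest cohort/manifest.tsv

$ gdvnet relevance --manifest cohort/manifest.tsv --threshold 0.2 --outdir relevance
persistent nodes: [1, 6, 12, 18, 24, 30]

$ gdvnet compare --manifest cohort/manifest.tsv --threshold 0.2 --seed 17 --outdir compare
cluster sizes: {1: 4, 2: 4}; overall mean silhouette 0.834
```

The persistent nodes are exactly the planted core (for a 30-node atlas the
default core sits at labels 1, 6, 12, 18, 24, 30). The persistence report
shows *why*: at threshold 0.2 the earliest column equivalence appears at
step k = 3 (comparison depth r−k+1 = 6 of r = 8 rows), where the orbit
columns O2, O11, O13, O33, O55 and O67 — the hub-like orbits, centres of
their graphlets — all share the same six top nodes:

```json
"0.2": {
  "earliest_step": 3,
  "depth": 6,
  "groups": [{"orbits": [2, 11, 13, 33, 55, 67],
              "nodes": [1, 6, 12, 18, 24, 30]}]
}
```

The comparison stage separates the two planted subpopulations perfectly
(4 + 4), with mean silhouette 0.834, and the permutation test ties the
split to the planted attribute (p = 0.023 at 1,000 permutations for this
tiny cohort).

Per-threshold outputs (`frequency_table.tsv`, `sorted_frequency.tsv`,
`sorted_nodes.tsv`, `output_table.tsv`), the GCD matrix, cluster/silhouette
table, a Newick dendrogram and JSON run records land in the chosen output
directories. Real cohorts follow the same manifest format: a TSV with
`subject_id`, `matrix_path` (square delimited numeric text, entries in
[−1,1]), and optional `sex`/`age` columns.

Other subcommands: `gdvnet catalog` (dump the graphlet/orbit catalog),
`gdvnet gdv` (orbit counts for one matrix), `gdvnet randomize`
(degree-preserving nulls).

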