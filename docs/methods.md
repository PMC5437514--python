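# Methods

This note records the model behind `netfp`, the parameters that matter, the
design choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## The fingerprint model

A network fingerprint is the vector of normalized similarity scores between
one query gene network and an ordered reference set of pathway networks.
The coordinate order is the manifest order of the reference set and is
never implicitly sorted; two fingerprints are comparable only when computed
against the same reference set in the same order.

Networks are modeled as undirected labeled graphs over opaque,
case-sensitive gene-ID strings. Direction, edge weights and ID-namespace
reconciliation are deliberately out of scope: the mapping and scoring steps
below never consume direction or weights, and mixed-namespace IDs are
treated as distinct strings (an optional two-column mapping table can be
applied at load time).

### Node–node mapping

Query and reference are merged into a single graph: both node sets (tagged
`Q:`/`R:`; a gene present in both networks becomes two tagged twin nodes),
all within-network edges, and cross edges for gene pairs with attribute
similarity ≥ τ. Clustering runs on the blended affinity

    s(i,j) = w_topo * Jaccard(N(i), N(j)) + (1 - w_topo) * sim(i,j)

where N(·) are merged-graph neighborhoods and sim is the gene-level
attribute similarity (for within-network pairs too, so densely annotated
gene groups can share a cluster). The Jaccard of two empty neighborhoods is
defined as 0: the absence of edges is no evidence of similarity.

The default clusterer is affinity propagation with damping 0.9, up to 1000
sweeps, and convergence declared when the exemplar set is stable for 50
sweeps. The diagonal preference defaults to the median off-diagonal
affinity, the conventional choice yielding a moderate number of exemplars.
One implementation detail matters: on *exactly symmetric* inputs — and
merged graphs are full of them, because a shared gene's twin nodes have
identical rows — the message updates reach a fixed point where both members
of a would-be pair sit precisely on the exemplar decision boundary
(r(k,k) + a(k,k) = 0) and the clustering collapses to singletons. Reference
implementations break such ties with random noise; to keep runs exactly
reproducible `netfp` instead adds a deterministic index-based jitter
smaller than 1e-9 of the affinity range. The same affinity matrix and
parameters therefore always produce the same mapping, and on block-
structured test instances the result stays within 5% (measured: 0.1%) of
the exhaustive exemplar-set optimum.

Alternatives: a greedy aligner that repeatedly pairs the globally most
similar unmatched (query, reference) genes until similarity falls below
`min_sim` (ties broken lexicographically, so results are independent of
input order), and an adapter that runs an external alignment program via a
command template and parses one cluster per line of prefixed node IDs.
External tools are never re-implemented.

### Scoring and normalization

A cluster containing nodes of both origins scores the best-match average of
gene similarity between its query side and reference side; single-origin
clusters score 0, and the raw network similarity is the unweighted mean
over *all* clusters. Counting unmixed clusters as zeros penalizes mappings
in which the networks barely mingle; dropping them would let one lucky
cluster dominate the score.

Raw scores are normalized against a permutation null. The null model is
**label permutation**: the query's topology is preserved exactly and its
node labels are resampled without replacement from the annotated gene pool.
Edge rewiring was rejected because the score depends on node attributes and
cross-network structure; relabeling isolates exactly the attribute signal
while holding topology fixed. This is the largest single reconstruction in
the package — the randomization scheme behind the published Z-scores is not
specified anywhere — and it is isolated in `randomize_query` should another
scheme be preferred. With n permutations (default 10 in fast mode, 100 in
normal mode), the coordinate is

    z = (raw - null_mean) / max(null_sd, 1e-8),  clipped to [-1000, 1000]

using the sample (n−1) standard deviation; the query side (not the
reference) is randomized. z is invariant under strictly increasing affine
transforms applied jointly to raw and null scores, and degenerates to ±1000
under zero null variance rather than overflowing.

Per-reference seeds derive from (master seed + reference index), so a scan
is reproducible and its result independent of evaluation order; fingerprint
JSON is serialized canonically (sorted keys, fixed separators) and is
byte-identical across reruns.

### Attribute similarity

Gene–gene similarity defaults to GO-style semantic similarity computed from
a supplied is_a DAG and gene→term annotations: term information content
IC(t) = −ln(coverage of t including descendants / universe), Lin's measure
2·IC(MICA)/(IC(t1)+IC(t2)) between terms, best-match average between genes.
No publication of the original scoring formula exists, so Lin + BMA was
*chosen* — bounded in [0,1] and the standard pairing for gene-level GO
similarity — and the scorer is a pluggable interface. IC is estimated from
the supplied annotation corpus itself (no external frequency tables); only
is_a edges are used; unannotated genes score 0 instead of being dropped, so
topology is preserved. Sequence-based similarity is supported only as a
precomputed matrix (three-column TSV), never computed from raw sequences.

### Enrichment and validation

Over-representation uses the exact upper-tail hypergeometric probability,
computed by tail summation in log space (gammaln + logsumexp), with
Benjamini–Hochberg step-up correction across tested sets (Bonferroni
available). The universe defaults to all annotated genes and is overridable
— enrichment p-values are universe-sensitive, so the choice is surfaced,
never implicit. Sets are intersected with the universe before testing and
only sets overlapping the query are tested.

The validation harness labels each reference pathway positive for a query
iff its BH-adjusted enrichment p-value is below α = 0.05, treats the
fingerprint z-scores as prediction scores for those labels, and reports the
ROC AUC via the Mann–Whitney identity with tied pairs credited 0.5, plus
the unweighted mean AUC across evaluable queries. Queries whose labels are
single-class are skipped with a warning. z (not raw) is the predictor by
default; a flag switches to raw for ablation.

## Synthetic benchmark

The generator builds a complete self-consistent world so that the pipeline
can be exercised without database access.

*Ontology.* A single-rooted DAG of `n_families` = 30 function families:
root → family head → 2 mid terms → 6 leaf terms (leaves attach to 1–2
mids). This mimics the branch structure of a real functional ontology at
miniature scale: two leaves of one family meet at an informative ancestor,
leaves of different families meet only at the root (IC 0). An earlier
design with fully uniform background annotation over a generic layered DAG
gave random gene pairs BMA ≈ 0.25 — an unrealistically flat similarity
landscape compared with real GO, where a random pair's annotations rarely
share an informative ancestor — and was replaced before the benchmark
defaults were frozen.

*Annotations.* A pool of 200 genes; each gene carries 2 leaf terms from one
uniformly chosen family. Random gene pairs then score ≈ 0.07 mean BMA,
same-family pairs score high.

*References.* 20 pathways of 10–15 genes sampled from the pool (overlap
between pathways arises naturally). Each pathway's topology is an
edge-probability 0.35 random graph repaired to connectivity and topped up
to ≥ 10 edges, so generated references always satisfy the reference-set
edge filter. Pathway r owns family r; 3 of its leaves are the pathway's
theme terms, and every pathway gene carries each theme term with
probability `coherence` = 0.8 — the single knob controlling separability.

*Queries.* `plant_query` keeps a retention fraction (default scenarios use
0.9) of a reference's nodes with their induced edges, adds 5 background
pool genes and 5 random noise edges, and repairs connectivity. The planted
reference ID is recorded in metadata as ground truth.

Identical parameters + seed give byte-identical universes.

**What passing tests show — and don't.** On this benchmark the planted
reference attains the top z coordinate in ≥ 70% of 20 planting seeds
(measured 80–100% across universe seeds) and fingerprint z-scores predict
enrichment labels with mean AUC ≥ 0.8 (measured ≈ 0.96–1.0). The benchmark
is an analog, not a reproduction, of validation against curated disease
datasets: real annotation corpora are deeper and noisier, real pathways
overlap far more heavily, and real queries are not literal subgraphs of any
reference. The synthetic results demonstrate that the pipeline's signal
path works end to end and that the permutation normalization preserves a
genuine planted signal at n_perm = 10; they do not certify accuracy on
biological data.

## Numerical choices and degenerate inputs

- ε = 1e-8 guards the z denominator; z clips at ±1000.
- Affinity-propagation jitter < 1e-9 of the affinity range (see above);
  if no exemplar emerges, the node with the best self-evidence is used.
- Median preference over an empty off-diagonal (n = 1) falls back to 0;
  a 1-node instance is its own single cluster.
- Greedy-aligner and fingerprint-diff ties break lexicographically.
- Hypergeometric tails are exact to < 1e-12 against rational-arithmetic
  enumeration for all universes N ≤ 25.
- Self-loops are dropped with a warning, duplicate edges collapsed; header
  lines in edge lists are recognized only from a fixed vocabulary of
  column names (a purely frequency-based heuristic can swallow a real
  first edge and break write/read round-trips).
- Problem sizes in the test-suite benchmark (20 references of 10–15 nodes,
  10 permutations, 20 + 10 queries) are the package's standard desk-scale
  conditions; larger studies scale linearly in references × permutations.

## Known limitations

- The merged-graph construction, affinity blend, and label-permutation null
  are declared reconstructions; the original method's exact choices are
  unpublished.
- Gene IDs are opaque: no cross-database identifier mapping is attempted.
- Affinity propagation costs O(n² · sweeps) per (query, reference) pair;
  queries far above the recommended 100 nodes become slow in normal mode.
- The enrichment labels used for validation depend on the declared
  universe and BH correction; with other choices the AUC baseline shifts.
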