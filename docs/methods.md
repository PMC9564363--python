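# Methods

## Abundance profiles and clustering

Raw spot densities are strictly positive, arbitrary-unit measurements of
each protein under the six bent-root conditions, in fixed order
(ABS-cx, BS-cx, BBS-cx, ABS-cv, BS-cv, BBS-cv). Normalization
`X = log2(x_i / x̄_protein)` centres each protein on its own mean, making
profiles invariant to per-protein scale; by construction the mean of `2^X`
over conditions is exactly 1 (asserted at 1e−9 in tests).

Profiles are clustered with Lloyd's k-means under Euclidean distance,
k-means++ seeding, and the best of 25 restarts by total within-cluster sum
of squares; scikit-learn's implementation stands behind this operation, with
per-cluster withinss recomputed on top. Determinism by seed is prioritised
over mimicking any particular legacy tool default, since random-restart
k-means is not reproducible anyway. k defaults to 6 — treated as a given of
the study design, not selected by silhouette or gap statistics. Cluster
labels are re-indexed by decreasing size (ties by fitted label) so that
labels are stable across runs; nearest-centroid assignment is verified as a
fixpoint after fitting. Empty-cluster repair follows the library's
relocate-to-farthest-point strategy.

A cluster "peaks" in every condition where its centroid is ≥ 0.3 log2 units
(boundary inclusive). Clusters peaking nowhere keep their members but seed
no subnetwork.

## Subnetwork construction

The interactome uses STRING's integer 0–1000 combined-score convention;
"high confidence" is combined_score ≥ 700. On reading, duplicate undirected
pairs collapse to the maximum score (conservative toward the filter) and
self-loops are dropped with a warning. A cluster-related subnetwork is the
cluster's proteins found in the filtered network (seeds) plus all their
first neighbours, with the **induced** edge set: neighbour–neighbour edges
are retained. The alternative (seed-incident edges only) was rejected
because clique-based scoring on star-only graphs degenerates to node degree;
the induced choice matches the select-neighbours-then-subnetwork idiom of
interactive network tools. This is a documented design choice, not a claim
about how any particular published network was built — hub scores are
sensitive to it. Seeds absent from the interactome are recorded in the
subnetwork's provenance, never silently dropped; isolated seeds stay in the
node list but never enter hub ranking.

## Enrichment

Annotations are closed over `is_a` ancestors (true-path rule) before any
counting; only `is_a` is honoured from OBO input, with `part_of` and other
relationship lines ignored and counted. The raw p-value of a term is the
hypergeometric upper tail P[X ≥ k] with population N, successes K, draws n
(scipy's survival function; verified against exhaustive subset enumeration
to 1e−12 for all N ≤ 12). One test family is one (subnetwork, namespace)
pair; m counts only terms represented in the study set (k ≥ 1), so the
Bonferroni factor is reproducible from the result list. Significance is the
strict inequality p_adj < alpha. The background universe defaults to the
genes with ≥ 1 propagated annotation in the namespace (the
annotated-domain convention of web enrichment tools); the study set is
intersected with it. Namespace roots are never reported (k = n, K = N
always).

## Semantic reduction

IC(t) = −ln p(t) with p(t) the propagated annotation frequency in the
pipeline's own corpus — not an external reference corpus — for
self-containedness. Similarity is Lin's measure with the MICA taken over
common subsumers including the terms themselves; terms whose only common
subsumer is the root (IC 0) get similarity 0. Lin is used where the
REVIGO-family default would be SimRel; the choice is a configuration-level
decision and the cutoff semantics are identical. Reduction is greedy:
repeatedly merge the most similar remaining pair with similarity strictly
above the cutoff (ties: lexicographically smallest pair), discarding the
member with the larger adjusted p (ties: larger annotation frequency, i.e.
the more general term; then lexicographically larger ID). Merge chains are
resolved so every discarded term maps to a surviving representative, and
survivors' pairwise similarity ≤ cutoff is asserted post hoc. Equivalence
with any specific web-tool run is not claimed — tie-breaking there is
unrecoverable.

## Overlap partition

Terms occurring in exactly one subnetwork's (reduced) set are specific to
it; terms in ≥ 2 are shared. The tiling identity
`Σ specific + shared = unique union` is enforced by the container itself.
An optional per-cell breakdown (every non-empty intersection combination)
is emitted alongside.

## Hub ranking

Maximal cliques are enumerated by Bron–Kerbosch with pivoting (networkx),
sorted (size descending, then member list) for deterministic output.
`MCC(v) = Σ (|C|−1)!` is accumulated in exact integer arithmetic — scores
grow factorially and exceed 64-bit floats already for cliques of ~21 nodes.
Ties are broken by degree, then node ID; the published studies this models
show unexplained ties, so determinism is imposed here. Isolated nodes score
0 and never rank. MCC is computed per subnetwork, never on the global
interactome, and ignores edge weights (topology only). Whether the top
three are mutually connected (hub triangle) is reported, not asserted — it
is data-dependent.

## Synthetic data

The generator's defaults are the study conditions: 66 proteins in six
clusters of sizes 12/4/11/3/16/20 around the published centroid matrix.
Noise is Gaussian in log2 space with sd 0.2 — the minimum pairwise centroid
distance is ≈ 2.28, keeping separation/noise above 10, the regime in which
exact label recovery (ARI = 1) is expected. No distributional description
of real spot densities was available, so Gaussian-in-log2 is a stated
assumption. Abundance rows are drawn in normalized space and
back-transformed around a 1000-density-unit per-protein base level
(rescaled so the row mean is exactly the base level), which guarantees
positivity and makes the normalization the generator's exact inverse up to
each row's own centering constant.

The PPI generator plants, per cluster, maximal cliques (default three of
size five) that pairwise overlap only at one designated hub — the cluster's
first protein — scored uniformly in [700, 1000]; cluster proteins beyond
clique capacity attach to the hub as single high-score edges. The planted
hub's MCC is therefore `Σ (size−1)! + #pendant edges` in closed form. The
background is Erdős–Rényi (default 40 nodes, edge probability 0.05, plus
background-to-planted pairs at the same rate) scored in [150, 699] — below
the confidence threshold by construction, so the filter's effect is exactly
known. Evidence-channel score combination is not modelled, only the
combined score.

The GO generator builds one rooted `is_a` DAG per namespace (40 terms,
depth 4 by default; each term one parent in the level above, a second with
probability 0.3, producing diamonds) and annotates genes to leaf terms at a
0.05 baseline rate, except one designated leaf per (subnetwork, namespace)
annotated among that subnetwork's genes at 0.9. All randomness flows from
one integer seed through three deterministically spawned sub-streams
(abundance, graph, annotations), so identical configs are byte-identical
on disk and regenerating one component never shifts another.

What the generator does **not** emulate: 2-DE spot detection artefacts,
missing values, technical replicates, scale-free interactome topology,
realistic GO DAG shape or annotation depth, or inter-gene annotation
correlation. Passing recovery tests therefore demonstrates the pipeline's
correctness on its stated model, not performance on real proteomes.

## Problem sizes and numerical choices

Oracle suites use exhaustive enumeration where it is exact and cheap:
all-subset clique enumeration on 200 random graphs with n ≤ 8, the
hypergeometric sweep over every (N, K, n, k) with N ≤ 12, a 200-replicate
no-signal simulation for the family-wise error rate, and 100 seeded studies
for planted-structure recovery. Monte-Carlo assertions allow two binomial
standard errors of slack; exact identities are asserted at 1e−9 (profile
normalization) and 1e−12 (hypergeometric tail). Degenerate inputs are
handled explicitly: empty study sets, clusters with no present seeds and
empty sector calls are errors or logged skips (never silent), k > n is
rejected, and ranking short-falls (fewer than k non-isolated nodes) are
flagged rather than padded.

## Known limitations

- ID mapping between proteomic spot identifiers and interactome protein IDs
  is out of scope; inputs must arrive pre-mapped, and unmapped seeds are
  only reported.
- Bonferroni is the only multiple-testing correction; no FDR or g:SCS.
- Lin similarity only; SimRel is a noted extension point.
- Only `is_a` semantics in the ontology; no `part_of`, no evidence codes.
- The published GO-term identities and hub MCC magnitudes of the motivating
  study depend on specific external database releases and are not
  reproduction targets; the embedded published tables (centroids, specific
  term lists, shared counts) are the worked-example surface.
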