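# Methods

## The diversity measure

For a node *j* of a simple undirected graph, every neighbor *i* with degree
k(i) ≥ 2 contributes the fraction of its other links that leave the closed
neighborhood of *j*:

    φ(j) = Σ_{i ∈ N(j)} δ_j(i) / (k(i) − 1),   δ_j(i) = k(i) − 1 − |N(i) ∩ N(j)|.

δ_j(i) counts the edges from *i* to nodes outside N(j) ∪ {j}: of i's k(i)
links, one returns to *j* and |N(i) ∩ N(j)| stay inside j's neighborhood.
Degree-1 neighbors contribute 0 (they have no other links, and the
denominator would be undefined). Two readings of "the neighborhood that links
leave" are possible — the neighbor's own, or the focal node's closed
neighborhood. We use the latter: it bounds every term in [0, 1], giving the
clean invariant 0 ≤ φ(j) ≤ degree(j), which matches the universal pattern
PD ≤ PE and MGD ≤ MGE in published symptom-diversity tables (the neighbor's
own neighborhood reading produces per-term values far above 1 on dense
graphs and is inconsistent with low-degree entries such as a diversity of
0.95 at degree 2). Closed forms used as test anchors: φ ≡ 0 on complete
graphs, φ(leaf) = 1 and φ(center) = 0 on stars.

φ is computed on unweighted topology. SCN edge weights (co-occurrence
counts) are kept for thresholds and reporting only, since the statistic is
defined through degrees and adjacency alone.

Aggregation to phenotypes: **PD/PE** are φ and degree of a symptom in the
co-occurrence network; **MGD/MGE** are the maximum φ and maximum degree over
the symptom's genes that map into the interactome (unmapped genes are counted
and excluded; a fully unmapped symptom is flagged rather than scored). The
MGD argmax is tie-broken lexicographically so outputs are deterministic. For
a symptom pair the same maxima are taken over the *shared* genes of the two
members; because a maximum over a subset can never exceed the maximum over
either superset, pair MGD ≤ min of the single MGDs holds identically — this
subset-max monotonicity is asserted for every synthetic pair in the tests.

## Networks

The symptom co-occurrence network treats each cluster record as one
observation: every unordered pair of distinct terms in a record adds 1 to
that edge's weight, and node occurrences count records per term. Within-record
duplicates are removed first (a term cannot co-occur with itself), singleton
records create isolated nodes. Records carry an optional chief symptom;
`include_chief` (default on) merges it into the record before pair
generation, reading a record as "chief symptom plus accompanying cluster".
The alternative reading (chief kept out of the record) is a flag, not a
silent guess, because source records of this shape are genuinely ambiguous.

The interactome is read from a scored edge list and filtered at
score ≥ 700 — the threshold is inclusive. Self-pairs are dropped and
reversed duplicates collapsed before the simple undirected graph is built.

## Statistics

* **Correlations** are Pearson r with the two-sided t-transform p-value
  (zero-variance inputs are an error, n ≥ 3 required).
* **Two-group comparisons** use the Mann–Whitney rank-sum test with the
  tie-corrected normal approximation, reporting both medians. The two-sided
  p is the default; a one-sided option exists because directional claims
  ("pairs have lower MGD") are sometimes the target. Published tables of
  this kind rarely name their test, so both conventions are surfaced rather
  than silently chosen.
* **Threshold proportions** are inclusive (value ≥ threshold), reported as
  percentages rounded half-up to two decimals — the rounding convention used
  for every displayed value, with full precision kept internally.
* **Shared-pair randomization.** The observed statistic is the number of SCN
  edges whose endpoint gene sets intersect. The null preserves both bipartite
  degree sequences (each symptom's gene count, each gene's symptom count) via
  edge swaps: every permutation restarts from the observed table and applies
  10 × |edges| random swap attempts, each accepted only when the two swapped
  edges do not already exist. Restarting per permutation, rather than
  continuing one chain, keeps null draws close to independent; with a
  sequential chain the combination of autocorrelation and a heavily tied
  discrete count statistic produced a measurably conservative empirical p in
  calibration experiments. The empirical p uses the (1 + hits)/(n_perm + 1)
  convention and can never be zero; a normal-approximation z p-value is
  reported alongside, clearly labeled, because analytically tiny p-values
  (far below 1/(n_perm+1)) are otherwise unreachable. Default n_perm = 1000.
  Because the count statistic is integer-valued, ties with the observed value
  make the empirical p conservative when the null distribution is narrow;
  calibration checks therefore use inputs whose count spread is wide (50
  phenotypes with 2–7 genes each over 100 genes, dense SCN).

* **Drug proximity.** A target is first-order for a symptom when its
  shortest-path distance to the symptom's gene set is ≤ 1, i.e. it is itself
  a symptom gene (distance 0) or a direct neighbor. DTN counts distinct such
  targets (targets shared by many drugs are deduplicated); drugs owning at
  least one counted target are tallied separately. Distances are multi-source
  breadth-first search — the unit-weight specialization of Dijkstra — since
  the thresholded interactome is treated as unweighted.

* **Enrichment** is the hypergeometric upper tail P[X ≥ k] for an overlap of
  k between the query (restricted to the universe) and a gene set. The
  default universe is the union of the collection's genes, the default
  enrichment flag is raw p < 0.05 with no multiple-testing correction —
  mirroring common practice for this analysis — and Benjamini–Hochberg is
  available behind a flag. Pathway-overlap counts for a symptom pair follow
  the n/N convention where N is the partner symptom's enriched count.
  Clustering of the binary pair × pathway matrix uses average linkage on
  Jaccard distances for rows and columns independently (standard clustermap
  behavior), deterministic given the matrix and parameters.

## Synthetic data

The generator produces every input the pipeline consumes — scored
interactome, CUI-level association table with a many-to-one term mapping,
cluster records with chief symptoms, drug–target table, GMT pathway
collection, category annotation, plus decoy association rows exercising the
semantic-type filter and drop-list path — reproducibly from a single seed
(per-stage child seeds, integer sampling paths).

Default desk-scale conditions: 300 gene-mapped symptoms (+60 clinical-only
terms), 2,000 genes, 2,000 cluster records, 100 drugs / 30 targets, a
preferential-attachment interactome with attachment parameter 8
(≈16,000 edges before score filtering, 20% of scores below the 700
threshold), gene-set sizes from a discrete power law (zipf exponent 3,
clipped to 5–25), record sizes 2 + Poisson(3). Generation completes in a few
seconds.

Planted structure:

* Each symptom has a heavy-tailed broadness weight (Pareto); record inclusion
  is proportional to it, so broad symptoms occur in many records and acquire
  high SCN degree and PD. Symptoms above the median weight are labeled broad
  (ground truth).
* With probability `diversity_coupling`, each gene of a broad symptom is
  drawn from the interactome's top-φ decile (weighted by φ); all remaining
  draws come from the background pool. At coupling 1 this plants the
  clinical↔molecular association the analysis is designed to detect; at 0,
  gene content is independent of broadness by construction.
* With probability `drug_proximity_bias`, a drug target is placed at
  distance ≤ 1 from a symptom gene chosen proportionally to φ; otherwise
  uniformly over the interactome.

Two design choices keep the null conditions clean, because the measured
quantities have a mechanical size confound: DTN grows with the size of a gene
set's one-hop neighborhood, and the maximum φ over a set grows with the set's
size and with lucky hub draws. Background sampling is therefore
degree-stratified (a set of size m draws one gene from each of m degree
quantile strata of the background pool), making neighborhood size a function
of set size only; set sizes are assigned independently of broadness; and the
target pool is small relative to the interactome so that, under uniform
placement, per-symptom target counts are dominated by sampling noise rather
than neighborhood size. The top-φ decile is reserved for the coupling
mechanism and excluded from background draws, which separates the planted
mechanism from background variation. Ground-truth labels (weights, broadness,
term gene sets, target placement) are emitted with the bundle so recovery
tests never re-derive the truth.

What the generator does *not* emulate: the linguistic content of real
clinical records, database-specific biases of curated association sets,
literature-coupled interactome noise, or realistic drug polypharmacology
(targets per drug are small and uniform). Passing planted-effect tests shows
the pipeline detects the modeled mechanism at desk scale; it does not certify
effect sizes on real data, where the size confounds deliberately removed here
are present.

## Numerical and degenerate-input conventions

Reported values are rounded half-up to two decimals, full precision kept and
written alongside. Percentages with a zero denominator are returned as
undefined and flagged, not zero. Empty query-after-universe-restriction,
zero-variance correlation inputs, fewer than 3 paired observations, absent
shortest-path sources and degenerate bipartite graphs (< 2 phenotypes or
genes) are explicit errors; an empty filtered association table is a warning,
because an empty result is a legitimate outcome of aggressive filtering.
Single-row matrices collapse to one cluster. The pipeline records per-stage
status, keeps running independent stages after a failure, and stamps every
bundle with the config hash and seed.

## Known limitations

* φ is O(Σ_j Σ_{i∈N(j)} min(deg)) via neighbor-set intersections; fine for
  graphs up to a few hundred thousand edges, not tuned for dense
  million-edge interactomes.
* The empirical randomization p is conservative when the null count
  distribution is narrow (discrete ties); the z approximation is reported
  alongside but assumes approximate normality of the null counts.
* Enrichment reimplements the plain hypergeometric test; web-service scores
  with modified statistics or curated backgrounds will not match numerically.
* The pair-vs-single median *direction* on synthetic data depends on which
  symptoms end up in shared-gene pairs (broad, hub-sharing symptoms are
  over-represented), so only the per-pair subset-max bound — not a median
  ordering — is asserted as an invariant.
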