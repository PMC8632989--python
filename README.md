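# symdiv — network diversity of symptom phenotypes

Most symptoms are non-specific: fatigue, headache or insomnia can accompany
dozens of unrelated diseases, which makes them weak diagnostic signals on
their own. `symdiv` quantifies that non-specificity on two scales and asks
how they relate:

* **clinical scale** — build a symptom clinical association network (SCN)
  from symptom-cluster records (each record is a set of co-occurring symptom
  terms; edge weights count co-occurrences) and measure each symptom's
  *phenotypic diversity* there;
* **molecular scale** — map each symptom to its associated genes, and measure
  the *molecular network diversity* of that gene set in a score-filtered
  protein–protein interaction (PPI) network.

The package is aimed at network-medicine and symptom-science researchers who
have (or want to simulate) symptom co-occurrence records, phenotype–gene
association tables, a STRING-style interactome, drug–target tables and
pathway collections.

## The diversity statistic

The diversity of a node *j* in a simple undirected graph is a
bridging-coefficient-style measure: every neighbor *i* contributes the
fraction of its other links that leave *j*'s closed neighborhood,

    φ(j) = Σ_{i ∈ N(j), k(i) ≥ 2}  δ_j(i) / (k(i) − 1),
    δ_j(i) = k(i) − 1 − |N(i) ∩ N(j)|,

where k(i) is the degree of *i* and N(·) a node's neighbor set. Each term
lies in [0, 1], so 0 ≤ φ(j) ≤ degree(j); φ is zero on complete graphs and
large for nodes whose many neighbors reach far outside. On the SCN, φ and
degree of a symptom are its **PD**/**PE** (phenotypic diversity / degree). On
the PPI network, a phenotype's **MGD**/**MGE** are the maximum φ / maximum
degree over its associated genes — diverse symptoms are those owning at least
one topologically diverse gene.

Around the statistic the package implements the comparative analyses:
Pearson correlations between the scales (PD~MGD, PE~MGE), shared-gene symptom
pairs with a degree-preserving bipartite randomization null, rank-sum
pair-vs-single comparisons and ≥-threshold proportions, first-order
drug-target counts (DTN) and their correlations with diversity, and a
case-study module (hypergeometric pathway enrichment, enriched-pathway
overlap, agglomerative clustering of the pair × pathway matrix, PPI
subnetwork export). A synthetic-data generator emulates all inputs at desk
scale with tunable planted effects, so every stage is testable without
proprietary data.

## Worked example

Run the full pipeline on a synthetic bundle with both planted effects at full
strength (coupling between clinical breadth and gene diversity = 1, drug
targets anchored near diverse symptom genes):

```bash
cat > config.yaml <<'YAML'
output_dir: out
seed: 1
synthetic:
  diversity_coupling: 1.0
  drug_proximity_bias: 1.0
n_perm: 999
YAML
symdiv run config.yaml
```

which prints:

```
symptom network diversity — results summary

config hash: 44d39ca0c4ac4052  seed: 1
associations: 1601 between 300 phenotypes and 854 genes (mean genes/phenotype 5.34, mean phenotypes/gene 1.87)
SCN: 360 nodes, 12110 links
PPI: 2000 proteins, 12755 interactions
PD~MGD: PCC=0.543 (p=2.17e-24); PE~MGE: PCC=0.454 (p=1.16e-16)
shared-gene pairs: observed 704 vs null mean 427.0 (empirical p=0.001, z p=2.82e-23)
pair vs single MGD medians: 85.69 vs 25.06 (p=4.86e-20)
DTN~MGD: PCC=0.783 (p=2e-63)
case study focal=S254: 2 pairs at co-occurrence >= threshold
stage second_class: skipped: no input
```

Reading the output: the planted coupling surfaces as a significant positive
PD~MGD correlation (clinically broad symptoms carry topologically diverse
genes); co-occurring symptom pairs share genes far more often than the
degree-preserving null expects (704 observed vs ≈427 under randomization);
and the anchored drug targets produce a strong DTN~MGD correlation. Setting
`diversity_coupling: 0` and `drug_proximity_bias: 0` instead gives
correlations statistically indistinguishable from zero. All tables (diversity
per node, molecular diversity per symptom, shared-gene pairs, proximity,
enrichment overlaps, cluster assignments) are written under `out/`, along
with GraphML exports and a `bundle.json` carrying every statistic plus
provenance (config hash, seed).

The same functionality is available as a library
(`symdiv.node_diversity`, `symdiv.all_node_diversity`,
`symdiv.enumerate_shared_gene_pairs`, `symdiv.shared_pair_randomization`, …)
and through the other CLI subcommands `symdiv generate`, `symdiv diversity`
(φ for any edge-list file) and `symdiv report`.

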