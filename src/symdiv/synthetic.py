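"""Synthetic generator for every pipeline input, with planted effects.

The generator emulates the statistical structure the analysis assumes at desk
scale: a heavy-tailed interactome, a curated phenotype-gene association table
reached through a many-to-one term mapping, symptom-cluster records whose
co-occurrence breadth is driven by per-term "broadness" weights, drug-target
tables, and pathway collections. Two planted effects are tunable:

* ``diversity_coupling`` — the probability that a broad symptom's genes are
  drawn from the reserved high-diversity (top-phi) pool of the interactome
  rather than the background pool. At 1 this plants the association between a
  symptom's clinical breadth (hence its phenotypic diversity) and the maximum
  diversity of its genes; at 0 the two are independent by construction.
* ``drug_proximity_bias`` — the probability that a drug target is placed at
  distance <= 1 from a symptom gene chosen proportionally to its diversity,
  rather than uniformly over the interactome.

Two design choices keep the null conditions clean. Background genes are
sampled degree-stratified (one gene per degree quantile stratum), so a gene
set's interactome neighborhood size is a function of its size only and does
not co-vary with its maximum diversity; and the target pool is small relative
to the interactome, so uniform placement leaves the first-order target count
dominated by sampling noise rather than by neighborhood size. Ground-truth
labels (broadness, weights, term gene sets, target placement) are returned so
planted-effect recovery can be scored without re-deriving the truth.

All sampling flows from ``numpy.random.default_rng`` seeded per stage from
``cfg.seed``, so identical configs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import networkx as nx
import numpy as np

from .data_io import (
    AssociationRecord,
    AssociationTable,
    CategoryAnnotation,
    ClusterRecordSet,
    DrugTargetTable,
    GeneSetCollection,
    InteractomeEdgeList,
    TermMapping,
    write_associations,
    write_category_annotation,
    write_cluster_records,
    write_drug_targets,
    write_gene_sets,
    write_interactome,
    write_term_mapping,
)
from .diversity import DiversityTable, all_node_diversity
from .graph_build import build_interactome_graph

logger = logging.getLogger("symdiv")

__all__ = [
    "SyntheticConfig",
    "SyntheticAssociations",
    "generate_interactome",
    "generate_associations",
    "generate_cluster_records",
    "generate_drug_targets",
    "generate_gene_sets",
    "generate_category_annotation",
    "write_synthetic_bundle",
]

# body-system categories used for the annotation table
_CATEGORIES = [
    "NSS", "HNS", "AS", "SITS", "NPS", "DSS", "RSCS",
    "MSS", "HISS", "GS", "USS", "NMDS", "CSS", "RSS",
]


@dataclass
class SyntheticConfig:
    """Desk-scale study conditions for the synthetic inputs."""

    seed: int = 0
    n_symptoms: int = 300
    n_genes: int = 2000
    n_records: int = 2000
    n_drugs: int = 100
    n_targets: int = 30
    ppi_model: str = "preferential-attachment"  # or "configuration", "random"
    ppi_attachment: int = 8          # BA attachment parameter (edges per new node)
    score_below_frac: float = 0.2    # fraction of edges scored below the threshold
    score_threshold: int = 700
    assoc_degree_exponent: float = 3.0  # zipf exponent for gene-set sizes
    assoc_min_genes: int = 5
    assoc_max_genes: int = 25
    hub_fraction: float = 0.1        # top-phi pool reserved for the coupling
    diversity_coupling: float = 0.5
    drug_proximity_bias: float = 0.5
    broad_fraction: float = 0.5      # fraction of symptoms labeled broad
    record_size_min: int = 2
    record_size_poisson: float = 3.0
    n_extra_terms: int = 60          # clinical-only terms without gene data
    cui_split_max: int = 3           # a term maps from 1..this many source ids
    n_decoy: int = 20                # junk association rows exercising the filters
    n_pathways: int = 50
    pathway_core_size: int = 10
    pathway_noise_genes: int = 5

    def __post_init__(self) -> None:
        for name in ("n_symptoms", "n_genes", "n_records", "n_drugs", "n_targets",
                     "ppi_attachment", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("diversity_coupling", "drug_proximity_bias", "score_below_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.ppi_attachment >= self.n_genes:
            raise ValueError("infeasible density: attachment >= n_genes")
        if self.n_symptoms * self.assoc_max_genes > self.n_symptoms * self.n_genes:
            raise ValueError("requested associations exceed n_symptoms * n_genes")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng(cfg: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stage]))


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------


def generate_interactome(cfg: SyntheticConfig) -> InteractomeEdgeList:
    """Scored interactome edge list with a heavy-tailed degree distribution.

    The default preferential-attachment model gives the degree heterogeneity
    that makes maximum-diversity statistics non-trivial; a configuration-model
    rewiring and an Erdos-Renyi graph are available as degree-matched /
    homogeneous alternatives. A ``score_below_frac`` fraction of edges is
    scored below the threshold so downstream filtering is exercised.
    """
    rng = _rng(cfg, 1)
    nx_seed = int(rng.integers(2**31 - 1))
    if cfg.ppi_model == "preferential-attachment":
        G = nx.barabasi_albert_graph(cfg.n_genes, cfg.ppi_attachment, seed=nx_seed)
    elif cfg.ppi_model == "configuration":
        base = nx.barabasi_albert_graph(cfg.n_genes, cfg.ppi_attachment, seed=nx_seed)
        seq = [d for _, d in base.degree()]
        G = nx.configuration_model(seq, seed=nx_seed)
        G = nx.Graph(G)
        G.remove_edges_from(nx.selfloop_edges(G))
    elif cfg.ppi_model == "random":
        n_edges = cfg.ppi_attachment * (cfg.n_genes - cfg.ppi_attachment)
        G = nx.gnm_random_graph(cfg.n_genes, n_edges, seed=nx_seed)
    else:
        raise ValueError(f"unknown ppi_model {cfg.ppi_model!r}")
    edges = sorted(tuple(sorted(e)) for e in G.edges())
    below = rng.random(len(edges)) < cfg.score_below_frac
    lo = rng.integers(400, cfg.score_threshold, size=len(edges))
    hi = rng.integers(cfg.score_threshold, 1000, size=len(edges))
    scores = np.where(below, lo, hi)
    out = [
        (_gene_name(a), _gene_name(b), int(s))
        for (a, b), s in zip(edges, scores)
    ]
    return InteractomeEdgeList(out)


# ---------------------------------------------------------------------------
# Associations + term mapping
# ---------------------------------------------------------------------------


@dataclass
class SyntheticAssociations:
    """CUI-level association table, its term mapping, and the ground truth."""

    table: AssociationTable          # source-id level, pre-merge
    mapping: TermMapping             # source id -> clinical term
    term_genes: dict[str, frozenset[str]]
    broad: dict[str, bool]           # clinical term -> planted broadness label
    weights: dict[str, float]        # clinical term -> occurrence weight
    drop_list: list[str]             # junk phenotype ids standing in for review


def generate_associations(
    cfg: SyntheticConfig, ppi_diversity: DiversityTable
) -> SyntheticAssociations:
    """Phenotype-gene associations with the tunable diversity coupling.

    Gene-set sizes follow a discrete power law (zipf, exponent
    ``assoc_degree_exponent``) clipped to [assoc_min_genes, assoc_max_genes].
    Broad symptoms draw each gene from the reserved top-phi pool with
    probability ``diversity_coupling`` (weighted by phi within the pool) and
    from the degree-stratified background otherwise; narrow symptoms always
    draw from the background. Set sizes are independent of broadness. Each
    term's gene set is then partitioned over 1..cui_split_max source ids and
    the many-to-one mapping emitted, mirroring how multiple vocabulary codes
    merge onto one clinical term.
    """
    rng = _rng(cfg, 2)
    genes = np.array(ppi_diversity.nodes())
    phi = np.array([ppi_diversity.phi[g] for g in genes])
    deg = np.array([ppi_diversity.degree[g] for g in genes])
    n_hub = max(1, int(round(cfg.hub_fraction * len(genes))))
    order = np.argsort(phi, kind="stable")
    hub_idx = order[-n_hub:]
    bg_idx = order[:-n_hub]
    bg_sorted = bg_idx[np.argsort(deg[bg_idx], kind="stable")]
    p_hub = phi[hub_idx] / phi[hub_idx].sum()

    n = cfg.n_symptoms
    terms = [f"S{i:03d}" for i in range(n)]
    weights = rng.pareto(1.5, n) + 1.0
    thresh = np.quantile(weights, 1.0 - cfg.broad_fraction)
    broad = weights > thresh
    sizes = np.clip(
        rng.zipf(cfg.assoc_degree_exponent, n) + cfg.assoc_min_genes - 1,
        cfg.assoc_min_genes,
        cfg.assoc_max_genes,
    )

    nbg = len(bg_sorted)
    term_genes: dict[str, frozenset[str]] = {}
    for s in range(n):
        m = int(sizes[s])
        gs: set[str] = set()
        if broad[s] and cfg.diversity_coupling > 0:
            k = int(rng.binomial(m, cfg.diversity_coupling))
            k = min(k, len(hub_idx))
            if k:
                picked = rng.choice(hub_idx, size=k, replace=False, p=p_hub)
                gs.update(str(genes[i]) for i in picked)
        # degree-stratified background fill: one draw per quantile stratum
        stratum = 0
        while len(gs) < m:
            lo = (stratum % m) * nbg // m
            hi = ((stratum % m) + 1) * nbg // m
            gs.add(str(genes[bg_sorted[int(rng.integers(lo, max(hi, lo + 1)))]]))
            stratum += 1
        term_genes[terms[s]] = frozenset(gs)

    # split each term over 1..cui_split_max source ids
    records: list[AssociationRecord] = []
    mapping: dict[str, str] = {}
    cui_counter = 0
    for s, term in enumerate(terms):
        gs = sorted(term_genes[term])
        k = int(rng.integers(1, cfg.cui_split_max + 1))
        k = min(k, len(gs))
        assignment = rng.integers(0, k, size=len(gs))
        assignment[:k] = np.arange(k)  # every source id gets >= 1 gene
        ids = []
        for j in range(k):
            cui = f"C{cui_counter:07d}"
            cui_counter += 1
            ids.append(cui)
            mapping[cui] = term
        for g, a in zip(gs, assignment):
            records.append(AssociationRecord(ids[int(a)], term, g, "T184"))

    # decoy rows: junk phenotypes removed by the semantic filter or drop list
    drop_list: list[str] = []
    for d in range(cfg.n_decoy):
        pid = f"D{d:07d}"
        g = str(genes[int(rng.integers(len(genes)))])
        if d % 2 == 0:
            records.append(AssociationRecord(pid, f"decoy {d}", g, "T047"))
        else:
            records.append(AssociationRecord(pid, f"decoy {d}", g, "T184"))
            drop_list.append(pid)

    table = AssociationTable(records)
    return SyntheticAssociations(
        table,
        TermMapping(mapping),
        term_genes,
        {t: bool(b) for t, b in zip(terms, broad)},
        {t: float(w) for t, w in zip(terms, weights)},
        drop_list,
    )


# ---------------------------------------------------------------------------
# Cluster records
# ---------------------------------------------------------------------------


def generate_cluster_records(
    cfg: SyntheticConfig, weights: Mapping[str, float]
) -> ClusterRecordSet:
    """Symptom-cluster records; inclusion probability proportional to weight.

    ``weights`` carries the broadness weight per clinical term (ground truth
    from :func:`generate_associations`); ``n_extra_terms`` clinical-only terms
    without gene data are added with weights from the same distribution, so
    the co-occurrence network also contains unmapped symptoms. Each record has
    a chief symptom plus accompanying members.
    """
    rng = _rng(cfg, 3)
    terms = sorted(weights)
    w = [float(weights[t]) for t in terms]
    for i in range(cfg.n_extra_terms):
        terms.append(f"X{i:03d}")
        w.append(float(rng.pareto(1.5) + 1.0))
    w = np.asarray(w)
    p = w / w.sum()
    n_terms = len(terms)
    records: list[frozenset[str]] = []
    chiefs: list[Optional[str]] = []
    for _ in range(cfg.n_records):
        k = int(cfg.record_size_min + rng.poisson(cfg.record_size_poisson))
        k = min(max(k, 1), n_terms)
        idx = rng.choice(n_terms, size=k, replace=False, p=p)
        members = [terms[i] for i in idx]
        chief = members[0]
        records.append(frozenset(members[1:]) or frozenset([chief]))
        chiefs.append(chief)
    return ClusterRecordSet(records, chiefs)


# ---------------------------------------------------------------------------
# Drug targets and pathway collections
# ---------------------------------------------------------------------------


def generate_drug_targets(
    cfg: SyntheticConfig,
    phenotype_genes: Mapping[str, frozenset[str]],
    ppi: nx.Graph,
    ppi_diversity: Optional[DiversityTable] = None,
) -> tuple[DrugTargetTable, dict[str, str]]:
    """Drug-target table with the tunable proximity bias.

    With probability ``drug_proximity_bias`` a target is an anchored
    placement: a symptom gene chosen proportionally to its diversity, or one
    of its direct neighbors (guaranteed distance <= 1 from a symptom gene).
    Otherwise the target is uniform over the interactome. Each target is
    assigned to one or more of ``n_drugs`` drugs. Returns the table plus the
    per-target placement labels ("anchored" / "uniform").
    """
    rng = _rng(cfg, 4)
    if ppi_diversity is None:
        ppi_diversity = all_node_diversity(ppi, "molecular")
    pool = sorted({g for gs in phenotype_genes.values() for g in gs if g in ppi})
    if not pool:
        raise ValueError("no phenotype gene present in the interactome")
    phi = np.array([ppi_diversity.phi[g] for g in pool])
    p_anchor = phi / phi.sum() if phi.sum() > 0 else None
    placement: dict[str, str] = {}
    targets: list[str] = []
    nodes = sorted(ppi.nodes)
    guard = 0
    while len(targets) < cfg.n_targets and guard < 100 * cfg.n_targets:
        guard += 1
        if rng.random() < cfg.drug_proximity_bias:
            anchor = str(rng.choice(pool, p=p_anchor))
            cand = [anchor] + sorted(ppi[anchor])
            t = cand[int(rng.integers(len(cand)))]
            label = "anchored"
        else:
            t = nodes[int(rng.integers(len(nodes)))]
            label = "uniform"
        if t not in placement:
            placement[t] = label
            targets.append(t)
    pairs: set[tuple[str, str]] = set()
    for i, t in enumerate(targets):
        # every target owned by at least one drug; drugs may share targets
        pairs.add((f"DR{i % cfg.n_drugs:04d}", t))
    extra = cfg.n_drugs * 2
    for _ in range(extra):
        d = int(rng.integers(cfg.n_drugs))
        t = targets[int(rng.integers(len(targets)))]
        pairs.add((f"DR{d:04d}", t))
    return DrugTargetTable(pairs), placement


def generate_gene_sets(cfg: SyntheticConfig, ppi: nx.Graph) -> GeneSetCollection:
    """Pathway collection: connected interactome neighborhoods plus noise genes."""
    rng = _rng(cfg, 5)
    nodes = sorted(ppi.nodes)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(cfg.n_pathways):
        seed_node = nodes[int(rng.integers(len(nodes)))]
        core = [seed_node]
        frontier = sorted(ppi[seed_node])
        while len(core) < cfg.pathway_core_size and frontier:
            nxt = frontier.pop(int(rng.integers(len(frontier))))
            if nxt in core:
                continue
            core.append(nxt)
            for u in ppi[nxt]:
                if u not in core:
                    frontier.append(u)
        noise = [nodes[int(rng.integers(len(nodes)))] for _ in range(cfg.pathway_noise_genes)]
        sets[f"PW{i:03d}"] = (
            "synthetic pathway neighborhood",
            frozenset(core) | frozenset(noise),
        )
    return GeneSetCollection(sets)


def generate_category_annotation(
    cfg: SyntheticConfig, terms: list[str]
) -> CategoryAnnotation:
    """Assign each term one of the body-system categories."""
    rng = _rng(cfg, 6)
    cats = {t: _CATEGORIES[int(rng.integers(len(_CATEGORIES)))] for t in sorted(terms)}
    return CategoryAnnotation(cats)


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------


def write_synthetic_bundle(cfg: SyntheticConfig, outdir: str | Path) -> dict:
    """Generate every input, write it in its standard format, emit a manifest.

    Returns the manifest (also written as ``manifest.json``): the full config,
    the file paths, and the ground-truth labels needed to score planted
    effects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edges = generate_interactome(cfg)
    kept = InteractomeEdgeList(
        [e for e in edges.edges if e[2] >= cfg.score_threshold]
    )
    ppi = build_interactome_graph(kept)
    ppi_div = all_node_diversity(ppi, "molecular")
    synth = generate_associations(cfg, ppi_div)
    records = generate_cluster_records(cfg, synth.weights)
    drugs, placement = generate_drug_targets(cfg, synth.term_genes, ppi, ppi_div)
    pathways = generate_gene_sets(cfg, ppi)
    categories = generate_category_annotation(cfg, sorted(synth.term_genes))

    paths = {
        "interactome": str(outdir / "interactome.tsv"),
        "associations": str(outdir / "associations.tsv"),
        "term_mapping": str(outdir / "term_mapping.tsv"),
        "cluster_records": str(outdir / "cluster_records.tsv"),
        "drug_targets": str(outdir / "drug_targets.tsv"),
        "gene_sets": str(outdir / "pathways.gmt"),
        "categories": str(outdir / "categories.tsv"),
        "drop_list": str(outdir / "drop_list.txt"),
    }
    write_interactome(edges, paths["interactome"])
    write_associations(synth.table, paths["associations"])
    write_term_mapping(synth.mapping, paths["term_mapping"])
    write_cluster_records(records, paths["cluster_records"])
    write_drug_targets(drugs, paths["drug_targets"])
    write_gene_sets(pathways, paths["gene_sets"])
    write_category_annotation(categories, paths["categories"])
    Path(paths["drop_list"]).write_text(
        "\n".join(synth.drop_list) + "\n", encoding="utf-8"
    )
    truth = {
        "broad": synth.broad,
        "weights": synth.weights,
        "term_genes": {t: sorted(g) for t, g in synth.term_genes.items()},
        "target_placement": placement,
    }
    truth_path = outdir / "ground_truth.json"
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2)
    manifest = {
        "config": cfg.to_dict(),
        "paths": paths,
        "ground_truth": str(truth_path),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("write_synthetic_bundle: wrote %d files to %s", len(paths) + 2, outdir)
    return manifest
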