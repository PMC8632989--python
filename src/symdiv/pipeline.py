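"""Config-driven end-to-end runner.

Executes the full analysis sequence on compliant inputs (or on a freshly
generated synthetic bundle): read and filter inputs, merge terms, build the
symptom co-occurrence network and its diversity (PD/PE), build the
interactome and its diversity, derive molecular diversity (MGD/MGE) per
phenotype, correlate the two scales, enumerate shared-gene pairs, run the
degree-preserving randomization test, compare pairs vs singles, optionally
compare a second phenotype class, score drug-target proximity, and run the
case-study enrichment / overlap / clustering for a focal symptom. Stage
failures are recorded and later independent stages still run. Every output
carries the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import networkx as nx
import pandas as pd
import yaml

from . import data_io, drug_proximity, enrichment, graph_build, stats, synthetic
from .diversity import (
    all_node_diversity,
    enumerate_shared_gene_pairs,
    gene_set_diversity,
)

logger = logging.getLogger("symdiv")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "format_report"]


@dataclass
class PipelineConfig:
    output_dir: str
    seed: int = 0
    inputs: dict[str, str] = field(default_factory=dict)
    synthetic: Optional[synthetic.SyntheticConfig] = None
    score_threshold: int = 700
    include_chief: bool = True
    semantic_type_filter: Optional[str] = "T184"
    drop_list_path: Optional[str] = None
    n_perm: int = 1000
    p_threshold: float = 0.05
    min_cooccurrence: int = 15
    high_value_threshold: float = 250.0
    focal_symptom: Optional[str] = None

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_OPTIONAL_INPUTS = ("drug_targets", "gene_sets", "categories", "second_associations")
_REQUIRED_INPUTS = ("associations", "term_mapping", "cluster_records", "interactome")


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML config; every problem is reported at once."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    if "output_dir" not in raw:
        errors.append("output_dir is required")
    syn = None
    if raw.get("synthetic") is not None:
        try:
            syn_kwargs = dict(raw["synthetic"] or {})
            syn_kwargs.setdefault("seed", raw.get("seed", 0))
            syn = synthetic.SyntheticConfig(**syn_kwargs)
        except (TypeError, ValueError) as exc:
            errors.append(f"synthetic: {exc}")
    inputs = dict(raw.get("inputs") or {})
    if syn is None:
        for key in _REQUIRED_INPUTS:
            if key not in inputs:
                errors.append(f"inputs.{key} is required when synthetic is absent")
    for key, p in inputs.items():
        if not Path(p).exists():
            errors.append(f"inputs.{key}: path does not exist: {p}")
    if raw.get("drop_list") and not Path(raw["drop_list"]).exists():
        errors.append(f"drop_list: path does not exist: {raw['drop_list']}")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return PipelineConfig(
        output_dir=raw["output_dir"],
        seed=int(raw.get("seed", 0)),
        inputs=inputs,
        synthetic=syn,
        score_threshold=int(raw.get("score_threshold", 700)),
        include_chief=bool(raw.get("include_chief", True)),
        semantic_type_filter=raw.get("semantic_type_filter", "T184"),
        drop_list_path=raw.get("drop_list"),
        n_perm=int(raw.get("n_perm", 1000)),
        p_threshold=float(raw.get("p_threshold", 0.05)),
        min_cooccurrence=int(raw.get("min_cooccurrence", 15)),
        high_value_threshold=float(raw.get("high_value_threshold", 250.0)),
        focal_symptom=raw.get("focal_symptom"),
    )


class ResultsBundle(dict):
    """Stage name -> results; plus ``provenance`` and per-stage ``status``."""

    def write_json(self, path: str | Path) -> None:
        stats.write_stats_json(dict(self), path)


def _corr_dict(c: stats.CorrelationResult) -> dict:
    return {"n": c.n, "pcc": c.pcc, "p_value": c.p_value}


def run_pipeline(cfg: PipelineConfig) -> ResultsBundle:  # noqa: C901
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ResultsBundle()
    status: dict[str, str] = {}
    bundle["provenance"] = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": dataclasses.asdict(cfg),
    }

    # -- stage: inputs -------------------------------------------------------
    inputs = dict(cfg.inputs)
    drop_list = None
    if cfg.synthetic is not None:
        manifest = synthetic.write_synthetic_bundle(cfg.synthetic, outdir / "synthetic")
        inputs = {**manifest["paths"], **inputs}
        drop_list = [
            s for s in Path(inputs["drop_list"]).read_text().split() if s
        ]
        bundle["synthetic_manifest"] = {"paths": manifest["paths"]}
    elif cfg.drop_list_path:
        drop_list = [
            s for s in Path(cfg.drop_list_path).read_text().split() if s
        ]

    assoc_raw = data_io.read_associations(
        inputs["associations"],
        semantic_type_filter=cfg.semantic_type_filter,
        drop_list=drop_list,
    )
    mapping = data_io.read_term_mapping(inputs["term_mapping"])
    records = data_io.read_cluster_records(inputs["cluster_records"])
    edge_list = data_io.read_interactome(inputs["interactome"], cfg.score_threshold)
    status["inputs"] = "ok"

    # -- stage: term mapping -------------------------------------------------
    assoc = data_io.apply_term_mapping(assoc_raw, mapping)
    bundle["associations"] = data_io.summarize_associations(assoc)
    status["term_mapping"] = "ok"

    # -- stage: SCN + phenotypic diversity ------------------------------------
    scn = graph_build.build_cooccurrence_network(records, cfg.include_chief)
    scn_div = all_node_diversity(scn, "phenotype")
    scn_div.write_tsv(outdir / "scn_diversity.tsv")
    graph_build.export_graphml(scn, outdir / "scn.graphml")
    bundle["scn"] = {
        "n_nodes": scn.number_of_nodes(),
        "n_links": scn.number_of_edges(),
    }
    status["scn"] = "ok"

    # -- stage: interactome + molecular diversity ----------------------------
    ppi = graph_build.build_interactome_graph(edge_list)
    ppi_div = all_node_diversity(ppi, "molecular")
    ppi_div.write_tsv(outdir / "ppi_diversity.tsv")
    bundle["ppi"] = {
        "n_nodes": ppi.number_of_nodes(),
        "n_edges": ppi.number_of_edges(),
    }
    status["ppi"] = "ok"

    # -- stage: MGD/MGE per phenotype -----------------------------------------
    mol_rows = []
    mol: dict[str, Any] = {}
    for term in assoc.phenotypes():
        gsd = gene_set_diversity(ppi_div, term, assoc.gene_set(term))
        mol[term] = gsd
        mol_rows.append(
            {
                "phenotype": term,
                "genes_total": gsd.genes_total,
                "genes_in_network": gsd.genes_in_network,
                "MGD": gsd.mgd,
                "MGE": gsd.mge,
                "argmax_gene": gsd.argmax_gene,
            }
        )
    data_io.write_table(pd.DataFrame(mol_rows), outdir / "molecular_diversity.tsv")
    status["molecular_diversity"] = "ok"

    # -- stage: cross-scale correlations --------------------------------------
    try:
        both = [
            t for t in assoc.phenotypes() if t in scn_div and mol[t].mgd is not None
        ]
        corr = {
            "PD_vs_MGD": _corr_dict(
                stats.pearson_correlation(
                    [scn_div.phi[t] for t in both], [mol[t].mgd for t in both]
                )
            ),
            "PE_vs_MGE": _corr_dict(
                stats.pearson_correlation(
                    [scn_div.degree[t] for t in both], [mol[t].mge for t in both]
                )
            ),
            "n_phenotypes": len(both),
        }
        bundle["correlations"] = corr
        status["correlations"] = "ok"
    except ValueError as exc:
        status["correlations"] = f"failed: {exc}"

    # -- stage: shared-gene pairs + randomization ------------------------------
    pairs = enumerate_shared_gene_pairs(scn, assoc, ppi_div)
    data_io.write_table(
        pd.DataFrame([p.to_row() for p in pairs]), outdir / "pairs.tsv"
    )
    bundle["pairs"] = {"n_shared_gene_pairs": len(pairs)}
    try:
        rand = stats.shared_pair_randomization(
            assoc, scn, n_perm=cfg.n_perm, seed=cfg.seed
        )
        bundle["randomization"] = {
            "observed": rand.observed,
            "null_mean": float(pd.Series(rand.null_counts).mean()),
            "null_q95": rand.null_quantile(0.95),
            "n_perm": rand.n_perm,
            "empirical_p": rand.empirical_p,
            "z_p": rand.z_p,
            "seed": rand.seed,
        }
        status["randomization"] = "ok"
    except ValueError as exc:
        status["randomization"] = f"failed: {exc}"

    # -- stage: pair-vs-single comparisons ------------------------------------
    try:
        single_mgd = [g.mgd for g in mol.values() if g.mgd is not None]
        single_mge = [g.mge for g in mol.values() if g.mge is not None]
        pair_mgd = [p.mgd for p in pairs if p.mgd is not None]
        pair_mge = [p.mge for p in pairs if p.mge is not None]
        if not pair_mgd:
            raise ValueError("no pair with mapped shared genes")
        thr = cfg.high_value_threshold
        bundle["pair_vs_single"] = {
            "MGD": dataclasses.asdict(
                stats.rank_sum_compare(pair_mgd, single_mgd, "two-sided")
            ),
            "MGE": dataclasses.asdict(
                stats.rank_sum_compare(pair_mge, single_mge, "two-sided")
            ),
            "MGD_one_sided_less": dataclasses.asdict(
                stats.rank_sum_compare(pair_mgd, single_mgd, "less")
            ),
            "high_value_threshold": thr,
            "prop_MGD_ge_pairs": stats.proportion_ge(pair_mgd, thr),
            "prop_MGD_ge_singles": stats.proportion_ge(single_mgd, thr),
            "prop_MGE_ge_pairs": stats.proportion_ge(pair_mge, thr),
            "prop_MGE_ge_singles": stats.proportion_ge(single_mge, thr),
        }
        status["pair_vs_single"] = "ok"
    except ValueError as exc:
        status["pair_vs_single"] = f"failed: {exc}"

    # -- stage: second phenotype class (e.g. diseases) -------------------------
    if "second_associations" in inputs:
        try:
            second = data_io.read_associations(inputs["second_associations"])
            smgd = [
                g.mgd
                for t in second.phenotypes()
                for g in [gene_set_diversity(ppi_div, t, second.gene_set(t))]
                if g.mgd is not None
            ]
            single_mgd = [g.mgd for g in mol.values() if g.mgd is not None]
            bundle["second_class_vs_symptoms"] = dataclasses.asdict(
                stats.rank_sum_compare(smgd, single_mgd, "two-sided")
            )
            status["second_class"] = "ok"
        except (ValueError, data_io.InputFormatError) as exc:
            status["second_class"] = f"failed: {exc}"
    else:
        status["second_class"] = "skipped: no input"

    # -- stage: drug proximity -------------------------------------------------
    if "drug_targets" in inputs:
        try:
            drugs = data_io.read_drug_targets(inputs["drug_targets"])
            prox = [
                drug_proximity.first_order_targets(ppi, t, assoc.gene_set(t), drugs)
                for t in assoc.phenotypes()
            ]
            drug_proximity.write_proximity_table(prox, outdir / "proximity.tsv")
            div_map = {
                t: (scn_div.phi[t], mol[t].mgd)
                for t in assoc.phenotypes()
                if t in scn_div and mol[t].mgd is not None
            }
            pcorr = drug_proximity.proximity_diversity_correlations(prox, div_map)
            bundle["proximity_correlations"] = {
                k: _corr_dict(v) for k, v in pcorr.items()
            }
            status["drug_proximity"] = "ok"
        except ValueError as exc:
            status["drug_proximity"] = f"failed: {exc}"
    else:
        status["drug_proximity"] = "skipped: no input"

    # -- stage: case study ------------------------------------------------------
    if "gene_sets" in inputs:
        try:
            collection = data_io.read_gene_sets(inputs["gene_sets"])
            focal = cfg.focal_symptom
            if focal is None:
                counts: dict[str, int] = {}
                for p in pairs:
                    counts[p.pair[0]] = counts.get(p.pair[0], 0) + 1
                    counts[p.pair[1]] = counts.get(p.pair[1], 0) + 1
                focal = max(sorted(counts), key=lambda t: counts[t]) if counts else None
            if focal is None:
                raise ValueError("no focal symptom available")
            focal_pairs = [p for p in pairs if focal in p.pair]
            case = enrichment.select_case_pairs(focal_pairs, cfg.min_cooccurrence)
            focal_enr = enrichment.enrich(
                assoc.gene_set(focal), collection,
                p_threshold=cfg.p_threshold, query_label=focal,
            )
            overlaps = []
            matrix_rows = {}
            for p in case:
                partner = p.pair[0] if p.pair[1] == focal else p.pair[1]
                try:
                    enr = enrichment.enrich(
                        assoc.gene_set(partner), collection,
                        p_threshold=cfg.p_threshold, query_label=partner,
                    )
                except ValueError:
                    continue
                ov = enrichment.overlap_enriched(enr, focal_enr)
                overlaps.append(ov)
                matrix_rows[f"{focal}|{partner}"] = {
                    name: 1 for name in ov.overlapped
                }
            bundle["case_study"] = {
                "focal_symptom": focal,
                "n_focal_pairs": len(focal_pairs),
                "n_case_pairs": len(case),
                "overlaps": [
                    {
                        "pair": list(o.pair),
                        "n_overlap": o.n_overlap,
                        "n_total": o.n_total,
                        "percentage": o.percentage,
                    }
                    for o in overlaps
                ],
            }
            data_io.write_table(
                pd.DataFrame(
                    [
                        {
                            "symptom": o.pair[0],
                            "focal": o.pair[1],
                            "n_overlap": o.n_overlap,
                            "n_total": o.n_total,
                            "percentage": o.percentage,
                        }
                        for o in overlaps
                    ]
                ),
                outdir / "case_overlaps.tsv",
            )
            mat = (
                pd.DataFrame.from_dict(matrix_rows, orient="index")
                .fillna(0)
                .astype(int)
                .sort_index()
            )
            if not mat.empty and mat.shape[1] > 0:
                clus = enrichment.cluster_pathway_matrix(mat)
                bundle["case_study"]["n_matrix_pathways"] = int(mat.shape[1])
                bundle["case_study"]["row_clusters"] = clus.row_labels
                data_io.write_table(
                    pd.DataFrame(
                        sorted(clus.row_labels.items()),
                        columns=["pair", "cluster"],
                    ),
                    outdir / "case_clusters.tsv",
                )
                # PPI subnetwork over the case pairs' symptom gene sets
                gsets = {}
                for p in case:
                    for t in p.pair:
                        if assoc.gene_set(t):
                            gsets[t] = set(assoc.gene_set(t))
                if gsets:
                    sub, _labels = graph_build.extract_subnetwork(ppi, gsets)
                    graph_build.export_graphml(sub, outdir / "case_subnetwork.graphml")
                    bundle["case_study"]["subnetwork"] = {
                        "n_nodes": sub.number_of_nodes(),
                        "n_edges": sub.number_of_edges(),
                    }
            status["case_study"] = "ok"
        except ValueError as exc:
            status["case_study"] = f"failed: {exc}"
    else:
        status["case_study"] = "skipped: no input"

    bundle["status"] = status
    bundle.write_json(outdir / "bundle.json")
    logger.info("run_pipeline: %s", "; ".join(f"{k}={v}" for k, v in status.items()))
    return bundle


def format_report(bundle: ResultsBundle) -> str:
    """Human-readable stage summary of a results bundle."""
    lines = ["symptom network diversity — results summary", ""]
    prov = bundle.get("provenance", {})
    lines.append(f"config hash: {prov.get('config_hash')}  seed: {prov.get('seed')}")
    if "associations" in bundle:
        a = bundle["associations"]
        lines.append(
            f"associations: {a['n_associations']} between {a['n_phenotypes']} "
            f"phenotypes and {a['n_genes']} genes "
            f"(mean genes/phenotype {a['mean_genes_per_phenotype_2dp']}, "
            f"mean phenotypes/gene {a['mean_phenotypes_per_gene_2dp']})"
        )
    if "scn" in bundle:
        lines.append(
            f"SCN: {bundle['scn']['n_nodes']} nodes, {bundle['scn']['n_links']} links"
        )
    if "ppi" in bundle:
        lines.append(
            f"PPI: {bundle['ppi']['n_nodes']} proteins, {bundle['ppi']['n_edges']} interactions"
        )
    if "correlations" in bundle:
        c = bundle["correlations"]
        lines.append(
            f"PD~MGD: PCC={c['PD_vs_MGD']['pcc']:.3f} (p={c['PD_vs_MGD']['p_value']:.3g}); "
            f"PE~MGE: PCC={c['PE_vs_MGE']['pcc']:.3f} (p={c['PE_vs_MGE']['p_value']:.3g})"
        )
    if "randomization" in bundle:
        r = bundle["randomization"]
        lines.append(
            f"shared-gene pairs: observed {r['observed']} vs null mean "
            f"{r['null_mean']:.1f} (empirical p={r['empirical_p']:.3g}, z p={r['z_p']:.3g})"
        )
    if "pair_vs_single" in bundle:
        pv = bundle["pair_vs_single"]
        lines.append(
            f"pair vs single MGD medians: {pv['MGD']['median_a']:.2f} vs "
            f"{pv['MGD']['median_b']:.2f} (p={pv['MGD']['p_value']:.3g})"
        )
    if "proximity_correlations" in bundle:
        pc = bundle["proximity_correlations"]
        lines.append(
            f"DTN~MGD: PCC={pc['DTN_vs_MGD']['pcc']:.3f} "
            f"(p={pc['DTN_vs_MGD']['p_value']:.3g})"
        )
    if "case_study" in bundle:
        cs = bundle["case_study"]
        lines.append(
            f"case study focal={cs['focal_symptom']}: {cs['n_case_pairs']} pairs "
            f"at co-occurrence >= threshold"
        )
    for k, v in bundle.get("status", {}).items():
        if v != "ok":
            lines.append(f"stage {k}: {v}")
    return "\n".join(lines) + "\n"
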