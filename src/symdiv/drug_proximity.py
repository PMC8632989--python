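"""Drug-target proximity in the interactome.

A drug target is "first order" for a symptom when it sits at shortest-path
distance <= 1 from the symptom's gene set: either it is itself a symptom gene
(distance 0) or a direct interactome neighbor of one (distance 1). DTN is the
number of distinct such targets; drugs owning at least one counted target are
tallied separately. The thresholded interactome is treated as unweighted, so
the shortest-path computation is breadth-first search (the unit-weight
specialization of Dijkstra's algorithm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd

from .data_io import DrugTargetTable
from .stats import CorrelationResult, pearson_correlation

logger = logging.getLogger("symdiv")

__all__ = [
    "shortest_path_lengths",
    "ProximityRecord",
    "first_order_targets",
    "proximity_diversity_correlations",
    "write_proximity_table",
]


def shortest_path_lengths(ppi: nx.Graph, sources: Iterable[str]) -> dict[str, int]:
    """Multi-source BFS distances from a gene set over unit-weight edges.

    Sources absent from the graph are skipped (logged); unreachable nodes are
    absent from the returned map. Raises when no source is in the graph.
    """
    present = [s for s in sources if s in ppi]
    missing = set(sources) - set(present)
    if missing:
        logger.info("shortest_path_lengths: %d sources not in graph", len(missing))
    if not present:
        raise ValueError("no source gene present in the interactome")
    return dict(nx.multi_source_dijkstra_path_length(ppi, present))


@dataclass(frozen=True)
class ProximityRecord:
    """First-order drug-target counts for one phenotype."""

    phenotype: str
    dtn: int
    n_drugs: int
    genes_in_network: int


def first_order_targets(
    ppi: nx.Graph,
    phenotype: str,
    phenotype_genes: Iterable[str],
    drugs: DrugTargetTable,
) -> ProximityRecord:
    """DTN and distinct-drug count at distance <= 1 from the gene set."""
    genes = [g for g in set(phenotype_genes) if g in ppi]
    neighborhood: set[str] = set(genes)
    for g in genes:
        neighborhood.update(ppi[g])
    counted = {t for t in drugs.targets if t in neighborhood}
    owning = {d for d, t in drugs.pairs if t in counted}
    return ProximityRecord(phenotype, len(counted), len(owning), len(genes))


def proximity_diversity_correlations(
    records: Iterable[ProximityRecord],
    diversity: Mapping[str, tuple[float, float]],
) -> dict[str, CorrelationResult]:
    """Correlate DTN and drug counts with phenotypic (PD) and molecular (MGD)
    diversity across phenotypes.

    ``diversity`` maps phenotype -> (PD, MGD). Only phenotypes present in both
    inputs enter; at least 3 are required.
    """
    recs = [r for r in records if r.phenotype in diversity]
    if len(recs) < 3:
        raise ValueError("need >= 3 phenotypes with both proximity and diversity")
    dtn = [r.dtn for r in recs]
    ndr = [r.n_drugs for r in recs]
    pd_ = [diversity[r.phenotype][0] for r in recs]
    mgd = [diversity[r.phenotype][1] for r in recs]
    return {
        "DTN_vs_MGD": pearson_correlation(dtn, mgd),
        "DTN_vs_PD": pearson_correlation(dtn, pd_),
        "n_drugs_vs_MGD": pearson_correlation(ndr, mgd),
        "n_drugs_vs_PD": pearson_correlation(ndr, pd_),
    }


def write_proximity_table(records: Iterable[ProximityRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "phenotype": r.phenotype,
                "DTN": r.dtn,
                "n_drugs": r.n_drugs,
                "genes_in_network": r.genes_in_network,
            }
            for r in records
        ]
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
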