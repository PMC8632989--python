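"""Node diversity and its phenotype-level aggregates.

The diversity of node *j* is a bridging-coefficient-style statistic: each
neighbor *i* contributes the fraction of its other links that leave the
closed neighborhood of *j*,

    phi(j) = sum over neighbors i with k(i) >= 2 of
             (k(i) - 1 - |N(i) ∩ N(j)|) / (k(i) - 1),

so every term lies in [0, 1] and 0 <= phi(j) <= degree(j). phi is 0 on
complete graphs (neighbors' other links never leave) and phi(leaf) = 1 on a
star with >= 2 leaves. Degree-1 neighbors contribute 0: they have no other
links.

Applied to the symptom co-occurrence network this is the phenotypic diversity
(PD, with PE the degree); applied to the interactome, a phenotype's molecular
diversity is the maximum phi over its associated genes (MGD, with MGE the
maximum degree).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import pandas as pd

from .data_io import AssociationTable, round_half_up

logger = logging.getLogger("symdiv")

__all__ = [
    "node_diversity",
    "all_node_diversity",
    "DiversityTable",
    "GeneSetDiversity",
    "gene_set_diversity",
    "PairDiversity",
    "enumerate_shared_gene_pairs",
]


def node_diversity(graph: nx.Graph, j) -> float:
    """Diversity phi of node ``j`` (see module docstring for the definition)."""
    if j not in graph:
        raise KeyError(f"node {j!r} not in graph")
    adj = graph._adj  # adjacency dicts; read-only use
    Nj = adj[j].keys()
    phi = 0.0
    for i in Nj:
        ki = len(adj[i])
        if ki < 2:
            continue
        common = sum(1 for u in adj[i] if u in Nj)
        # links of i minus the link back to j minus links into N(j)
        phi += (ki - 1 - common) / (ki - 1)
    return phi


@dataclass
class DiversityTable:
    """Per-node diversity and degree for one graph.

    ``graph_tag`` records which network the entries refer to ("phenotype" or
    "molecular"); entries are full precision, rounding happens at write time.
    """

    phi: dict
    degree: dict
    graph_tag: str = ""

    def __post_init__(self) -> None:
        if set(self.phi) != set(self.degree):
            raise ValueError("phi and degree must cover the same nodes")

    def __len__(self) -> int:
        return len(self.phi)

    def __contains__(self, node) -> bool:
        return node in self.phi

    def nodes(self) -> list:
        return sorted(self.phi)

    def to_frame(self) -> pd.DataFrame:
        """Sorted by diversity descending, with rank and 2-dp display values."""
        df = pd.DataFrame(
            {
                "node": list(self.phi),
                "degree": [self.degree[n] for n in self.phi],
                "diversity": [self.phi[n] for n in self.phi],
            }
        )
        df = df.sort_values(
            ["diversity", "node"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        df["rank"] = df.index + 1
        df["diversity_2dp"] = [round_half_up(v, 2) for v in df["diversity"]]
        return df

    def write_tsv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, sep="\t", index=False)


def all_node_diversity(graph: nx.Graph, graph_tag: str = "") -> DiversityTable:
    """phi and degree for every node of a simple graph."""
    adj = graph._adj
    phi: dict = {}
    for j in graph.nodes:
        Nj = adj[j].keys()
        s = 0.0
        for i in Nj:
            ki = len(adj[i])
            if ki < 2:
                continue
            common = sum(1 for u in adj[i] if u in Nj)
            s += (ki - 1 - common) / (ki - 1)
        phi[j] = s
    degree = {n: graph.degree(n) for n in graph.nodes}
    return DiversityTable(phi, degree, graph_tag)


@dataclass(frozen=True)
class GeneSetDiversity:
    """Molecular network diversity of one phenotype's gene set.

    MGD/MGE are the maximum diversity / maximum degree over the genes present
    in the interactome; ``argmax_gene`` attains MGD (ties broken
    lexicographically). When no gene maps into the network the record is
    flagged ``unmapped`` and MGD/MGE are None.
    """

    phenotype: str
    genes_total: int
    genes_in_network: int
    mgd: Optional[float]
    mge: Optional[int]
    argmax_gene: Optional[str]

    @property
    def unmapped(self) -> bool:
        return self.genes_in_network == 0


def gene_set_diversity(
    ppi_diversity: DiversityTable, phenotype: str, genes: Iterable[str]
) -> GeneSetDiversity:
    """MGD/MGE of ``phenotype`` over the genes present in the interactome."""
    genes = set(genes)
    if not genes:
        raise ValueError("gene set is empty")
    mapped = sorted(g for g in genes if g in ppi_diversity)
    if not mapped:
        return GeneSetDiversity(phenotype, len(genes), 0, None, None, None)
    best_phi = max(ppi_diversity.phi[g] for g in mapped)
    # deterministic argmax: lexicographically first gene attaining the max
    argmax = min(g for g in mapped if ppi_diversity.phi[g] == best_phi)
    mge = max(ppi_diversity.degree[g] for g in mapped)
    return GeneSetDiversity(phenotype, len(genes), len(mapped), best_phi, mge, argmax)


@dataclass(frozen=True)
class PairDiversity:
    """A shared-gene symptom pair: an SCN edge whose endpoints share genes."""

    pair: tuple[str, str]
    shared_genes: frozenset[str]
    mgd: Optional[float]
    mge: Optional[int]
    argmax_gene: Optional[str]
    cooccurrence_weight: int

    def to_row(self) -> dict:
        return {
            "symptom_a": self.pair[0],
            "symptom_b": self.pair[1],
            "n_shared": len(self.shared_genes),
            "MGD": self.mgd,
            "MGE": self.mge,
            "argmax_gene": self.argmax_gene,
            "cooccurrence": self.cooccurrence_weight,
        }


def enumerate_shared_gene_pairs(
    scn: nx.Graph,
    assoc: AssociationTable,
    ppi_diversity: Optional[DiversityTable] = None,
) -> list[PairDiversity]:
    """All SCN edges whose two endpoints have intersecting gene sets.

    A pair is emitted only when the intersection is non-empty. When a
    ``ppi_diversity`` table is supplied the pair's MGD/MGE are computed over
    the shared genes (max over a subset, hence never above either single
    phenotype's MGD); otherwise they are left as None.
    """
    pairs: list[PairDiversity] = []
    for a, b, data in scn.edges(data=True):
        ga = assoc.index.get(a)
        gb = assoc.index.get(b)
        if not ga or not gb:
            continue
        shared = ga & gb
        if not shared:
            continue
        key = (a, b) if str(a) <= str(b) else (b, a)
        if ppi_diversity is not None:
            gsd = gene_set_diversity(ppi_diversity, f"{key[0]}|{key[1]}", shared)
            mgd, mge, am = gsd.mgd, gsd.mge, gsd.argmax_gene
        else:
            mgd = mge = am = None
        pairs.append(
            PairDiversity(key, frozenset(shared), mgd, mge, am, data.get("weight", 1))
        )
    pairs.sort(key=lambda p: p.pair)
    logger.info("enumerate_shared_gene_pairs: %d shared-gene pairs", len(pairs))
    return pairs
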