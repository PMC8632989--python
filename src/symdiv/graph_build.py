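"""Construction of the symptom co-occurrence network and the interactome graph.

The symptom clinical association network (SCN) is an undirected graph whose
nodes are symptom terms and whose edge weights count how many cluster records
contain both endpoints. The interactome (PPI) graph is the simple undirected
graph of the score-filtered edge list. Both are plain ``networkx.Graph``
objects so that downstream metrics compose with the standard toolkit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Optional

import networkx as nx

from .data_io import ClusterRecordSet, InteractomeEdgeList, round_half_up

logger = logging.getLogger("symdiv")

__all__ = [
    "build_cooccurrence_network",
    "build_interactome_graph",
    "extract_subnetwork",
    "pair_cooccurrence",
    "PairCooccurrence",
    "export_graphml",
    "export_edgelist",
]


def build_cooccurrence_network(
    records: ClusterRecordSet, include_chief: bool = True
) -> nx.Graph:
    """Build the SCN from cluster records.

    Every unordered pair of distinct terms within a record (including the
    chief symptom when ``include_chief``) adds 1 to that edge's ``weight``.
    Each node carries an ``occurrence`` attribute: the number of records the
    term appears in. Singleton records contribute an isolated node. Terms are
    deduplicated within a record, so a term never co-occurs with itself.
    """
    if len(records) == 0:
        raise ValueError("record set is empty")
    G = nx.Graph()
    occurrence: dict[str, int] = {}
    for rec in records.effective_records(include_chief):
        terms = sorted(rec)
        for t in terms:
            occurrence[t] = occurrence.get(t, 0) + 1
            if t not in G:
                G.add_node(t)
        for a, b in combinations(terms, 2):
            if G.has_edge(a, b):
                G[a][b]["weight"] += 1
            else:
                G.add_edge(a, b, weight=1)
    nx.set_node_attributes(G, occurrence, "occurrence")
    logger.info(
        "build_cooccurrence_network: %d records -> %d nodes, %d links",
        len(records),
        G.number_of_nodes(),
        G.number_of_edges(),
    )
    return G


def build_interactome_graph(edges: InteractomeEdgeList) -> nx.Graph:
    """Simple undirected PPI graph from a cleaned edge list."""
    G = nx.Graph()
    for a, b, _score in edges.edges:
        G.add_edge(a, b)
    logger.info(
        "build_interactome_graph: %d proteins, %d interactions",
        G.number_of_nodes(),
        G.number_of_edges(),
    )
    return G


def extract_subnetwork(
    ppi: nx.Graph, gene_sets: Mapping[str, set[str]]
) -> tuple[nx.Graph, dict[str, list[str]]]:
    """Induced subgraph on the union of the given gene sets.

    Returns the subgraph plus a node -> sorted list of set names containing
    it (multi-membership is common for shared genes of a symptom cluster).
    """
    if not gene_sets or all(not s for s in gene_sets.values()):
        raise ValueError("gene sets are empty")
    union: set[str] = set()
    for s in gene_sets.values():
        union |= set(s)
    present = union & set(ppi.nodes)
    if not present:
        logger.warning("extract_subnetwork: no gene present in the interactome")
    sub = ppi.subgraph(present).copy()
    labels = {
        n: sorted(name for name, s in gene_sets.items() if n in s) for n in sub.nodes
    }
    nx.set_node_attributes(sub, {n: "|".join(v) for n, v in labels.items()}, "sets")
    return sub, labels


@dataclass(frozen=True)
class PairCooccurrence:
    """Co-occurrence of s1 with s2: n = records with both, N = records with s1."""

    s1: str
    s2: str
    n: int
    N: int

    @property
    def percentage(self) -> Optional[float]:
        """n/N as a percentage, 2 decimals; None when s1 never occurs."""
        if self.N == 0:
            return None
        return round_half_up(100.0 * self.n / self.N, 2)


def pair_cooccurrence(
    records: ClusterRecordSet, s1: str, s2: str, include_chief: bool = True
) -> PairCooccurrence:
    """Count records containing both terms and records containing ``s1``."""
    recs = records.effective_records(include_chief)
    N = sum(1 for r in recs if s1 in r)
    n = sum(1 for r in recs if s1 in r and s2 in r)
    if N == 0:
        logger.warning("pair_cooccurrence: %r never occurs; percentage undefined", s1)
    return PairCooccurrence(s1, s2, n, N)


def export_graphml(G: nx.Graph, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(G, path)


def export_edgelist(G: nx.Graph, path: str | Path) -> None:
    """Plain TSV edge list (source, target, weight-if-present)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for a, b, data in G.edges(data=True):
            fh.write(f"{a}\t{b}\t{data.get('weight', '')}\n")
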