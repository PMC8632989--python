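"""Over-representation analysis, enriched-pathway overlap, and clustering.

Enrichment is a hypergeometric upper-tail test: the probability of drawing at
least the observed overlap between a query gene set and a pathway when the
query is sampled without replacement from the gene universe. By default raw
p < 0.05 flags a pathway enriched, with Benjamini-Hochberg correction
available behind a flag. Pairwise overlap of enriched pathway names and
agglomerative clustering of the pair x pathway membership matrix support the
symptom-cluster case study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_io import GeneSetCollection, round_half_up
from .diversity import PairDiversity

logger = logging.getLogger("symdiv")

__all__ = [
    "EnrichmentResult",
    "enrich",
    "PathwayOverlap",
    "overlap_enriched",
    "select_case_pairs",
    "ClusteringResult",
    "cluster_pathway_matrix",
]


@dataclass
class EnrichmentResult:
    """Per-pathway hypergeometric results for one query gene set.

    ``rows`` columns: set_name, overlap, query_size, set_size, universe_size,
    p_value, (p_adjusted when corrected), enriched.
    """

    query: str
    rows: pd.DataFrame
    threshold: float
    collection_id: int

    def enriched_names(self) -> frozenset[str]:
        return frozenset(self.rows.loc[self.rows["enriched"], "set_name"])


def enrich(
    genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Optional[Iterable[str]] = None,
    p_threshold: float = 0.05,
    query_label: str = "query",
    correct: bool = False,
) -> EnrichmentResult:
    """Hypergeometric over-representation of ``genes`` in every named set.

    The query is restricted to the universe before testing (default universe:
    union of collection genes). For each set of size m in a universe of size
    N, with a query of size n overlapping k genes, the p-value is
    P[X >= k] for X ~ Hypergeometric(N, m, n). With ``correct=True``
    Benjamini-Hochberg adjusted p-values decide the enriched flag instead of
    raw ones.
    """
    uni = frozenset(universe) if universe is not None else collection.universe
    for name in collection.sets:
        extra = collection.genes(name) - uni
        if extra:
            raise ValueError(
                f"universe must contain every tested set; {name!r} has "
                f"{len(extra)} genes outside it"
            )
    query = frozenset(genes) & uni
    if not query:
        raise ValueError("query has no gene in the universe")
    N, n = len(uni), len(query)
    rows = []
    for name in collection.names():
        members = collection.genes(name)
        m = len(members)
        k = len(query & members)
        # upper tail P[X >= k] = sf(k-1)
        p = float(sps.hypergeom.sf(k - 1, N, m, n)) if k > 0 else 1.0
        rows.append((name, k, n, m, N, min(p, 1.0)))
    df = pd.DataFrame(
        rows,
        columns=["set_name", "overlap", "query_size", "set_size", "universe_size", "p_value"],
    )
    if correct:
        from statsmodels.stats.multitest import multipletests

        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["enriched"] = df["p_adjusted"] < p_threshold
    else:
        df["enriched"] = df["p_value"] < p_threshold
    return EnrichmentResult(query_label, df, p_threshold, id(collection))


@dataclass(frozen=True)
class PathwayOverlap:
    """Enriched-pathway overlap of a symptom with a focal symptom.

    ``n_overlap``/``n_total`` follow the n/N (%) convention: N is the number
    of pathways enriched in the (non-focal) partner symptom.
    """

    pair: tuple[str, str]
    overlapped: frozenset[str]
    n_overlap: int
    n_total: int

    @property
    def percentage(self) -> Optional[float]:
        if self.n_total == 0:
            return None
        return round_half_up(100.0 * self.n_overlap / self.n_total, 2)


def overlap_enriched(a: EnrichmentResult, b: EnrichmentResult) -> PathwayOverlap:
    """Pathways enriched in both ``a`` (the partner symptom) and ``b`` (focal).

    Both results must come from the same collection; N in the reported n/N
    convention is the partner's (``a``'s) enriched count.
    """
    if a.collection_id != b.collection_id:
        raise ValueError("enrichment results computed against different collections")
    ea, eb = a.enriched_names(), b.enriched_names()
    shared = ea & eb
    return PathwayOverlap((a.query, b.query), frozenset(shared), len(shared), len(ea))


def select_case_pairs(
    pairs: Sequence[PairDiversity], min_cooccurrence: int
) -> list[PairDiversity]:
    """Pairs with co-occurrence weight >= threshold, heaviest first."""
    kept = [p for p in pairs if p.cooccurrence_weight >= min_cooccurrence]
    kept.sort(key=lambda p: (-p.cooccurrence_weight, p.pair))
    return kept


@dataclass
class ClusteringResult:
    row_labels: dict
    col_labels: dict
    row_linkage: Optional[np.ndarray]
    col_linkage: Optional[np.ndarray]
    method: str
    metric: str


def _cluster_axis(
    X: np.ndarray, names: Sequence, n_clusters: Optional[int], cut_height: Optional[float],
    method: str, metric: str,
) -> tuple[dict, Optional[np.ndarray]]:
    if len(names) == 1:
        return {names[0]: 1}, None
    d = pdist(X.astype(bool), metric=metric)
    Z = hierarchy.linkage(d, method=method)
    if n_clusters is not None:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    elif cut_height is not None:
        labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    else:
        labels = hierarchy.fcluster(Z, t=0.5 * d.max() if d.max() > 0 else 1.0,
                                    criterion="distance")
    return dict(zip(names, (int(v) for v in labels))), Z


def cluster_pathway_matrix(
    matrix: pd.DataFrame,
    n_clusters: Optional[int] = None,
    cut_height: Optional[float] = None,
    method: str = "average",
    metric: str = "jaccard",
) -> ClusteringResult:
    """Agglomerative clustering of a binary pair x pathway membership matrix.

    Rows (symptom pairs) and columns (pathways) are clustered independently
    with average linkage on Jaccard distances of the binary profiles —
    the behavior of a standard clustermap. Deterministic given the matrix and
    parameters; single-row or single-column axes collapse to one cluster.
    """
    if matrix.empty:
        raise ValueError("membership matrix is empty")
    X = matrix.to_numpy()
    row_labels, row_Z = _cluster_axis(
        X, list(matrix.index), n_clusters, cut_height, method, metric
    )
    col_labels, col_Z = _cluster_axis(
        X.T, list(matrix.columns), n_clusters, cut_height, method, metric
    )
    return ClusteringResult(row_labels, col_labels, row_Z, col_Z, method, metric)
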