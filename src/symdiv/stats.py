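"""Comparative statistics: correlations, rank-sum median comparisons,
threshold proportions, and the shared-gene randomization test.

The randomization test asks whether co-occurring symptom pairs share
associated genes more often than expected if genes were assigned at random
while preserving how many genes each symptom has and how many symptoms each
gene has. The null is generated by degree-preserving edge swaps on the
bipartite phenotype-gene graph; both an empirical p-value (never zero, using
the (1 + hits)/(n_perm + 1) convention) and a normal-approximation z p-value
are reported.
"""

from __future__ import annotations

import json
import logging
import math
import random
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from .data_io import AssociationTable, round_half_up
from .diversity import enumerate_shared_gene_pairs

logger = logging.getLogger("symdiv")

__all__ = [
    "CorrelationResult",
    "pearson_correlation",
    "GroupComparison",
    "rank_sum_compare",
    "proportion_ge",
    "RandomizationResult",
    "shared_pair_randomization",
    "write_stats_json",
]

Tail = Literal["two-sided", "greater", "less"]


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    pcc: float
    p_value: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.pcc <= 1.0 + 1e-12):
            raise ValueError("correlation outside [-1, 1]")


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with a two-sided p-value from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(int(x.size), float(r), float(p))


@dataclass(frozen=True)
class GroupComparison:
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    tail: str


def rank_sum_compare(
    a: Sequence[float], b: Sequence[float], tail: Tail = "two-sided"
) -> GroupComparison:
    """Mann-Whitney/Wilcoxon rank-sum comparison of two samples.

    Uses the tie-corrected normal approximation and reports both medians.
    ``tail="less"`` tests whether ``a`` is stochastically smaller than ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative=tail, method="asymptotic")
    return GroupComparison(
        float(np.median(a)),
        float(np.median(b)),
        int(a.size),
        int(b.size),
        float(res.statistic),
        float(res.pvalue),
        tail,
    )


def proportion_ge(values: Sequence[float], threshold: float) -> float:
    """Percentage of values >= threshold (inclusive), 2 decimals half-up."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    return round_half_up(100.0 * float(np.mean(values >= threshold)), 2)


@dataclass
class RandomizationResult:
    observed: int
    null_counts: list[int]
    n_perm: int
    empirical_p: float
    z_p: float
    seed: int
    tail: str = "greater"

    def null_quantile(self, q: float) -> float:
        return float(np.quantile(self.null_counts, q))


def _bipartite_edge_swap(
    edges: list[tuple[str, str]],
    edge_set: set[tuple[str, str]],
    rng: random.Random,
    n_swaps: int,
) -> None:
    """In-place degree-preserving rewiring of a bipartite edge list.

    Each attempt picks two edges (p1,g1),(p2,g2) and swaps the gene ends when
    the swapped edges do not already exist; both bipartite degree sequences
    are invariant under every accepted swap.
    """
    m = len(edges)
    for _ in range(n_swaps):
        i = rng.randrange(m)
        j = rng.randrange(m)
        if i == j:
            continue
        p1, g1 = edges[i]
        p2, g2 = edges[j]
        if g1 == g2 or p1 == p2:
            continue
        e1, e2 = (p1, g2), (p2, g1)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard((p1, g1))
        edge_set.discard((p2, g2))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2


def _count_shared_pairs(
    scn_edges: list[tuple[str, str]], index: dict[str, set[str]]
) -> int:
    n = 0
    for a, b in scn_edges:
        ga = index.get(a)
        gb = index.get(b)
        if ga and gb:
            small, large = (ga, gb) if len(ga) <= len(gb) else (gb, ga)
            if any(g in large for g in small):
                n += 1
    return n


def shared_pair_randomization(
    assoc: AssociationTable,
    scn: nx.Graph,
    n_perm: int = 1000,
    seed: int = 0,
    swap_factor: int = 10,
    tail: Tail = "greater",
) -> RandomizationResult:
    """Permutation test for the number of shared-gene SCN pairs.

    The observed statistic is the number of SCN edges whose endpoint gene
    sets intersect. Each permutation rewires the bipartite association graph
    with ``swap_factor * n_edges`` degree-preserving swaps and recounts.
    Fully reproducible from ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    edges = [(r.phenotype_id, r.gene) for r in assoc.records]
    if len(edges) < 2:
        raise ValueError("degree-preserving shuffle infeasible: < 2 associations")
    phen_ids = {p for p, _ in edges}
    gene_ids = {g for _, g in edges}
    if len(phen_ids) < 2 or len(gene_ids) < 2:
        raise ValueError(
            "degree-preserving shuffle infeasible: degenerate bipartite graph"
        )
    observed = len(enumerate_shared_gene_pairs(scn, assoc))
    scn_edges = [(a, b) for a, b in scn.edges()]
    rng = random.Random(seed)
    null_counts: list[int] = []
    n_swaps = swap_factor * len(edges)
    for _ in range(n_perm):
        # each permutation rewires afresh from the observed table
        perm_edges = list(edges)
        edge_set = set(perm_edges)
        _bipartite_edge_swap(perm_edges, edge_set, rng, n_swaps)
        index: dict[str, set[str]] = {}
        for p, g in perm_edges:
            index.setdefault(p, set()).add(g)
        null_counts.append(_count_shared_pairs(scn_edges, index))
    nulls = np.asarray(null_counts)
    if tail == "greater":
        hits = int(np.sum(nulls >= observed))
    elif tail == "less":
        hits = int(np.sum(nulls <= observed))
    else:
        mu = float(nulls.mean())
        hits = int(np.sum(np.abs(nulls - mu) >= abs(observed - mu)))
    empirical_p = (1 + hits) / (n_perm + 1)
    mu, sd = float(nulls.mean()), float(nulls.std(ddof=1)) if n_perm > 1 else 0.0
    if sd > 0:
        z = (observed - mu) / sd
        if tail == "greater":
            z_p = float(sps.norm.sf(z))
        elif tail == "less":
            z_p = float(sps.norm.cdf(z))
        else:
            z_p = float(2 * sps.norm.sf(abs(z)))
    else:
        # degenerate null: all permutations give the same count
        if observed == mu:
            z_p = 1.0
        elif tail == "greater":
            z_p = 0.0 if observed > mu else 1.0
        elif tail == "less":
            z_p = 0.0 if observed < mu else 1.0
        else:
            z_p = 0.0
    logger.info(
        "shared_pair_randomization: observed=%d, null mean=%.1f, empirical p=%.3g",
        observed,
        mu,
        empirical_p,
    )
    return RandomizationResult(
        observed, null_counts, n_perm, empirical_p, z_p, seed, tail
    )


def write_stats_json(results: dict, path: str | Path) -> None:
    """Serialize a dict of statistic dataclasses / plain values as JSON."""

    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2, default=default)
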