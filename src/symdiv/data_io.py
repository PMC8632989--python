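"""Readers, writers and validators for the tabular inputs of the analysis.

All tables are UTF-8 delimited text (TSV unless noted); clinical terms may be
non-ASCII. Readers accept plain or gzip-compressed files (by ``.gz`` suffix,
handled by pandas). The association table is the central object: a bipartite
phenotype <-> gene relation with per-entity set indexes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger("symdiv")

__all__ = [
    "InputFormatError",
    "AssociationRecord",
    "AssociationTable",
    "TermMapping",
    "ClusterRecordSet",
    "InteractomeEdgeList",
    "DrugTargetTable",
    "GeneSetCollection",
    "CategoryAnnotation",
    "read_associations",
    "apply_term_mapping",
    "read_term_mapping",
    "read_interactome",
    "read_cluster_records",
    "read_drug_targets",
    "read_gene_sets",
    "read_category_annotation",
    "summarize_associations",
    "write_associations",
    "write_term_mapping",
    "write_interactome",
    "write_cluster_records",
    "write_drug_targets",
    "write_gene_sets",
    "write_category_annotation",
    "write_table",
    "round_half_up",
]


class InputFormatError(ValueError):
    """A delimited input file does not match its declared schema."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention used in reported tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationRecord:
    """One phenotype–gene association row."""

    phenotype_id: str
    phenotype_label: str
    gene: str
    semantic_type: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.phenotype_id or not self.gene:
            raise ValueError("phenotype_id and gene must be non-empty")


class AssociationTable:
    """Deduplicated set of phenotype–gene associations with both set indexes.

    ``index`` maps phenotype_id -> frozenset of genes and ``reverse_index``
    maps gene -> frozenset of phenotype_ids; the two are exact inverses and
    the record count equals the sum of gene-set sizes.
    """

    def __init__(self, records: Iterable[AssociationRecord]):
        seen: dict[tuple[str, str], AssociationRecord] = {}
        for r in records:
            seen.setdefault((r.phenotype_id, r.gene), r)
        self.records: list[AssociationRecord] = sorted(
            seen.values(), key=lambda r: (r.phenotype_id, r.gene)
        )
        index: dict[str, set[str]] = {}
        reverse: dict[str, set[str]] = {}
        labels: dict[str, str] = {}
        for r in self.records:
            index.setdefault(r.phenotype_id, set()).add(r.gene)
            reverse.setdefault(r.gene, set()).add(r.phenotype_id)
            labels.setdefault(r.phenotype_id, r.phenotype_label)
        self.index: dict[str, frozenset[str]] = {
            p: frozenset(g) for p, g in index.items()
        }
        self.reverse_index: dict[str, frozenset[str]] = {
            g: frozenset(p) for g, p in reverse.items()
        }
        self.labels = labels

    # -- basic counts ------------------------------------------------------
    @property
    def n_phenotypes(self) -> int:
        return len(self.index)

    @property
    def n_genes(self) -> int:
        return len(self.reverse_index)

    @property
    def n_associations(self) -> int:
        return len(self.records)

    def gene_set(self, phenotype_id: str) -> frozenset[str]:
        return self.index.get(phenotype_id, frozenset())

    def phenotypes(self) -> list[str]:
        return sorted(self.index)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationTable):
            return NotImplemented
        return self.records == other.records

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phenotype_id": [r.phenotype_id for r in self.records],
                "phenotype_label": [r.phenotype_label for r in self.records],
                "gene": [r.gene for r in self.records],
                "semantic_type": [r.semantic_type or "" for r in self.records],
            }
        )


@dataclass
class TermMapping:
    """Many-to-one map from source phenotype ids to merged clinical terms."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        # dict keys are unique by construction; targets may repeat freely
        self.entries = dict(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ClusterRecordSet:
    """Symptom-cluster records: one set of co-occurring terms per record.

    ``chief`` optionally carries the chief symptom each cluster was filed
    under; whether the chief participates in co-occurrence is decided at
    network-build time.
    """

    records: list[frozenset[str]]
    chief: Optional[list[Optional[str]]] = None

    def __post_init__(self) -> None:
        self.records = [frozenset(r) for r in self.records]
        if any(len(r) < 1 for r in self.records):
            raise ValueError("every record needs at least one distinct term")
        if self.chief is not None and len(self.chief) != len(self.records):
            raise ValueError("chief list length must match records")

    def __len__(self) -> int:
        return len(self.records)

    def effective_records(self, include_chief: bool = True) -> list[frozenset[str]]:
        """Records with the chief symptom merged in when requested."""
        if not include_chief or self.chief is None:
            return list(self.records)
        out = []
        for rec, c in zip(self.records, self.chief):
            out.append(rec | {c} if c else rec)
        return out


@dataclass
class InteractomeEdgeList:
    """Score-filtered undirected interactome edges (cleaned, deduplicated)."""

    edges: list[tuple[str, str, int]]

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class DrugTargetTable:
    """Unique (drug_id, target_gene) pairs."""

    pairs: set[tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = {
            (d, g) for d, g in self.pairs if d and g
        }

    @property
    def drugs(self) -> set[str]:
        return {d for d, _ in self.pairs}

    @property
    def targets(self) -> set[str]:
        return {g for _, g in self.pairs}

    def targets_of(self, drug: str) -> set[str]:
        return {g for d, g in self.pairs if d == drug}

    def __len__(self) -> int:
        return len(self.pairs)


class GeneSetCollection:
    """Named gene sets (pathways / GO terms) with a gene universe."""

    def __init__(
        self,
        sets: Mapping[str, tuple[str, frozenset[str]]],
        universe: Optional[frozenset[str]] = None,
    ):
        for name, (_, genes) in sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets: dict[str, tuple[str, frozenset[str]]] = dict(sets)
        if universe is None:
            u: set[str] = set()
            for _, genes in self.sets.values():
                u |= genes
            universe = frozenset(u)
        self.universe = frozenset(universe)

    def genes(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return sorted(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and self.universe == other.universe


@dataclass
class CategoryAnnotation:
    """Term -> body-system category (each term in exactly one category)."""

    entries: dict[str, str]

    def categories(self) -> set[str]:
        return set(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise InputFormatError(f"{path}: empty file") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing required columns {missing}")
    return df


def read_associations(
    path: str | Path,
    semantic_type_filter: Optional[str] = None,
    drop_list: Optional[Iterable[str]] = None,
) -> AssociationTable:
    """Read a phenotype–gene association TSV, filter and deduplicate.

    ``semantic_type_filter`` keeps only rows whose semantic_type matches
    (row-wise; e.g. the symptom-and-sign category of a concept vocabulary).
    ``drop_list`` removes whole phenotypes (by id or by label) — it stands in
    for a manual review of terms without clear symptom meaning. An empty
    result is returned with a warning, not raised.
    """
    df = _read_tsv(path, ["phenotype_id", "phenotype_label", "gene"])
    n_raw = len(df)
    if semantic_type_filter is not None:
        if "semantic_type" not in df.columns:
            raise InputFormatError(
                f"{path}: semantic_type filter requested but column absent"
            )
        df = df[df["semantic_type"] == semantic_type_filter]
    if drop_list:
        drop = set(drop_list)
        df = df[~df["phenotype_id"].isin(drop) & ~df["phenotype_label"].isin(drop)]
    dropped = n_raw - len(df)
    records = [
        AssociationRecord(
            r.phenotype_id,
            r.phenotype_label,
            r.gene,
            getattr(r, "semantic_type", None) or None,
        )
        for r in df.itertuples(index=False)
    ]
    table = AssociationTable(records)
    logger.info(
        "read_associations: %d raw rows, %d dropped by filters, %d unique associations",
        n_raw,
        dropped,
        table.n_associations,
    )
    if table.n_associations == 0:
        logger.warning("read_associations: %s produced an empty table", path)
    return table


def read_term_mapping(path: str | Path) -> TermMapping:
    df = _read_tsv(path, ["source_id", "term"])
    entries: dict[str, str] = {}
    for r in df.itertuples(index=False):
        if r.source_id in entries and entries[r.source_id] != r.term:
            raise InputFormatError(
                f"{path}: source {r.source_id} mapped to multiple terms"
            )
        entries[r.source_id] = r.term
    return TermMapping(entries)


def apply_term_mapping(assoc: AssociationTable, mapping: TermMapping) -> AssociationTable:
    """Merge phenotypes onto clinical terms; the merged gene set is the union.

    Phenotypes without a mapping entry are dropped (they have no clinical-term
    counterpart in the co-occurrence data); mapping sources absent from the
    table are ignored. Both counts are logged.
    """
    absent = [s for s in mapping.entries if s not in assoc.index]
    if absent:
        logger.info("apply_term_mapping: %d mapping sources not in table", len(absent))
    merged: list[AssociationRecord] = []
    unmapped = 0
    for pid, genes in assoc.index.items():
        term = mapping.entries.get(pid)
        if term is None:
            unmapped += 1
            continue
        for g in sorted(genes):
            merged.append(AssociationRecord(term, term, g))
    logger.info(
        "apply_term_mapping: %d phenotypes dropped as unmapped, %d terms kept",
        unmapped,
        len({mapping.entries[p] for p in assoc.index if p in mapping.entries}),
    )
    return AssociationTable(merged)


def read_interactome(path: str | Path, score_threshold: int = 700) -> InteractomeEdgeList:
    """Read a scored edge list and keep edges with score >= threshold.

    Self-pairs are removed; duplicate and reversed-duplicate edges collapse to
    a single undirected edge (keeping the first-seen score).
    """
    df = _read_tsv(path, ["protein_a", "protein_b", "score"])
    try:
        scores = df["score"].astype(int)
    except ValueError as exc:
        raise InputFormatError(f"{path}: non-integer score value") from exc
    kept: dict[tuple[str, str], int] = {}
    n_self = 0
    for a, b, s in zip(df["protein_a"], df["protein_b"], scores):
        if a == b:
            n_self += 1
            continue
        if s < score_threshold:
            continue
        key = (a, b) if a < b else (b, a)
        kept.setdefault(key, int(s))
    logger.info(
        "read_interactome: %d rows, %d self-pairs removed, %d edges at score >= %d",
        len(df),
        n_self,
        len(kept),
        score_threshold,
    )
    return InteractomeEdgeList([(a, b, s) for (a, b), s in sorted(kept.items())])


def read_cluster_records(path: str | Path) -> ClusterRecordSet:
    """Read symptom-cluster records: columns ``chief`` and pipe-joined ``members``."""
    df = _read_tsv(path, ["chief", "members"])
    records, chiefs = [], []
    for r in df.itertuples(index=False):
        terms = frozenset(t for t in r.members.split("|") if t)
        if not terms and not r.chief:
            raise InputFormatError(f"{path}: record with no terms")
        records.append(terms or frozenset([r.chief]))
        chiefs.append(r.chief or None)
    return ClusterRecordSet(records, chiefs if any(chiefs) else None)


def read_drug_targets(path: str | Path) -> DrugTargetTable:
    df = _read_tsv(path, ["drug_id", "target_gene"])
    return DrugTargetTable(
        {(r.drug_id, r.target_gene) for r in df.itertuples(index=False)}
    )


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB gene1 TAB gene2 ..."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with opener(path, "rt", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputFormatError(f"{path}:{ln}: GMT line needs >= 3 fields")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise InputFormatError(f"{path}:{ln}: gene set {name!r} is empty")
            sets[name] = (desc, frozenset(genes))
    return GeneSetCollection(sets)


def read_category_annotation(path: str | Path) -> CategoryAnnotation:
    df = _read_tsv(path, ["term", "category"])
    entries: dict[str, str] = {}
    for r in df.itertuples(index=False):
        if r.term in entries and entries[r.term] != r.category:
            raise InputFormatError(f"{path}: term {r.term!r} in two categories")
        entries[r.term] = r.category
    return CategoryAnnotation(entries)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


def summarize_associations(assoc: AssociationTable) -> dict:
    """Counts, mean genes/phenotype, mean phenotypes/gene, degree histograms.

    Means are returned both at full precision and rounded half-up to two
    decimals, the precision used in reported tables.
    """
    if assoc.n_associations == 0:
        raise ValueError("cannot summarize an empty association table")
    mean_gpp = assoc.n_associations / assoc.n_phenotypes
    mean_ppg = assoc.n_associations / assoc.n_genes
    genes_per_phen = Counter(len(g) for g in assoc.index.values())
    phens_per_gene = Counter(len(p) for p in assoc.reverse_index.values())
    return {
        "n_phenotypes": assoc.n_phenotypes,
        "n_genes": assoc.n_genes,
        "n_associations": assoc.n_associations,
        "mean_genes_per_phenotype": mean_gpp,
        "mean_genes_per_phenotype_2dp": round_half_up(mean_gpp, 2),
        "mean_phenotypes_per_gene": mean_ppg,
        "mean_phenotypes_per_gene_2dp": round_half_up(mean_ppg, 2),
        "genes_per_phenotype_hist": dict(sorted(genes_per_phen.items())),
        "phenotypes_per_gene_hist": dict(sorted(phens_per_gene.items())),
    }


# ---------------------------------------------------------------------------
# Writers (round-trip partners of the readers above)
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_associations(assoc: AssociationTable, path: str | Path) -> None:
    write_table(assoc.to_frame(), path)


def write_term_mapping(mapping: TermMapping, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(mapping.entries.items()), columns=["source_id", "term"]
    )
    write_table(df, path)


def write_interactome(edges: InteractomeEdgeList, path: str | Path) -> None:
    df = pd.DataFrame(edges.edges, columns=["protein_a", "protein_b", "score"])
    write_table(df, path)


def write_cluster_records(records: ClusterRecordSet, path: str | Path) -> None:
    chiefs = records.chief or [None] * len(records)
    df = pd.DataFrame(
        {
            "chief": [c or "" for c in chiefs],
            "members": ["|".join(sorted(r)) for r in records.records],
        }
    )
    write_table(df, path)


def write_drug_targets(table: DrugTargetTable, path: str | Path) -> None:
    df = pd.DataFrame(sorted(table.pairs), columns=["drug_id", "target_gene"])
    write_table(df, path)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names():
            desc, genes = collection.sets[name]
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def write_category_annotation(ann: CategoryAnnotation, path: str | Path) -> None:
    df = pd.DataFrame(sorted(ann.entries.items()), columns=["term", "category"])
    write_table(df, path)
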