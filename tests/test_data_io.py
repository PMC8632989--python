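import gzip

import pandas as pd
import pytest

from symdiv import data_io
from symdiv.data_io import (
    AssociationRecord,
    AssociationTable,
    ClusterRecordSet,
    DrugTargetTable,
    GeneSetCollection,
    InputFormatError,
    InteractomeEdgeList,
    TermMapping,
    apply_term_mapping,
    read_associations,
    read_interactome,
    round_half_up,
    summarize_associations,
)


def write_assoc_tsv(path, rows, header="phenotype_id\tphenotype_label\tgene\tsemantic_type"):
    path.write_text(header + "\n" + "\n".join("\t".join(r) for r in rows) + "\n")


class TestReadAssociations:
    def test_deduplicates_repeated_pairs(self, tmp_path):
        rows = [
            ("P1", "fever", "A", "T184"),
            ("P1", "fever", "A", "T184"),
            ("P1", "fever", "B", "T184"),
            ("P2", "rash", "A", "T184"),
            ("P2", "rash", "A", "T184"),
        ]
        f = tmp_path / "a.tsv"
        write_assoc_tsv(f, rows)
        table = read_associations(f)
        assert table.n_associations == 3

    def test_semantic_type_filter_keeps_matching_rows(self, tmp_path):
        rows = [
            ("P1", "fever", "A", "T184"),
            ("P2", "lung edema", "B", "T047"),
            ("P3", "rash", "C", "T184"),
        ]
        f = tmp_path / "a.tsv"
        write_assoc_tsv(f, rows)
        table = read_associations(f, semantic_type_filter="T184")
        assert sorted(table.index) == ["P1", "P3"]

    def test_drop_list_matches_line_by_line_recount(self, tmp_path, rng):
        phens = [f"P{i:02d}" for i in range(25)]
        genes = [f"G{i:02d}" for i in range(40)]
        rows = []
        for _ in range(100):
            p = phens[rng.integers(len(phens))]
            rows.append((p, f"label {p}", genes[rng.integers(len(genes))], "T184"))
        drop = set(phens[:10])
        f = tmp_path / "a.tsv"
        write_assoc_tsv(f, rows)
        table = read_associations(f, drop_list=drop)
        # independent recount over the raw file
        expected = {
            (p, g) for p, _lbl, g, _st in rows if p not in drop
        }
        assert table.n_associations == len(expected)
        assert set(table.index) == {p for p, _ in expected}

    def test_missing_column_raises(self, tmp_path):
        f = tmp_path / "a.tsv"
        f.write_text("phenotype_id\tgene\nP1\tA\n")
        with pytest.raises(InputFormatError):
            read_associations(f)

    def test_empty_result_warns_not_raises(self, tmp_path, caplog):
        f = tmp_path / "a.tsv"
        write_assoc_tsv(f, [("P1", "fever", "A", "T047")])
        table = read_associations(f, semantic_type_filter="T184")
        assert table.n_associations == 0

    def test_gzip_input(self, tmp_path):
        f = tmp_path / "a.tsv.gz"
        content = "phenotype_id\tphenotype_label\tgene\nP1\tfever\tA\n"
        with gzip.open(f, "wt") as fh:
            fh.write(content)
        assert read_associations(f).n_associations == 1


class TestTermMapping:
    def test_union_of_gene_sets(self):
        table = AssociationTable(
            [
                AssociationRecord("C1", "x", "A"),
                AssociationRecord("C1", "x", "B"),
                AssociationRecord("C2", "y", "B"),
                AssociationRecord("C2", "y", "C"),
            ]
        )
        merged = apply_term_mapping(table, TermMapping({"C1": "fever", "C2": "fever"}))
        assert merged.gene_set("fever") == {"A", "B", "C"}

    def test_identity_mapping_preserves_table(self):
        table = AssociationTable(
            [AssociationRecord(p, p, g) for p, g in [("a", "X"), ("b", "Y")]]
        )
        merged = apply_term_mapping(table, TermMapping({"a": "a", "b": "b"}))
        assert merged.index == table.index

    def test_unmapped_phenotypes_dropped(self):
        table = AssociationTable(
            [AssociationRecord("C1", "x", "A"), AssociationRecord("C2", "y", "B")]
        )
        merged = apply_term_mapping(table, TermMapping({"C1": "fever"}))
        assert merged.phenotypes() == ["fever"]

    def test_random_mapping_matches_brute_force_union(self, rng):
        records = []
        for i in range(30):
            for _ in range(int(rng.integers(1, 6))):
                records.append(
                    AssociationRecord(f"C{i}", f"lbl{i}", f"G{rng.integers(50)}")
                )
        table = AssociationTable(records)
        mapping = {f"C{i}": f"T{i // 3}" for i in range(30)}
        merged = apply_term_mapping(table, TermMapping(mapping))
        for term in merged.phenotypes():
            expected = set()
            for cui, t in mapping.items():
                if t == term:
                    expected |= set(table.gene_set(cui))
            assert merged.gene_set(term) == expected


class TestReadInteractome:
    def test_threshold_is_inclusive(self, tmp_path):
        f = tmp_path / "ppi.tsv"
        f.write_text(
            "protein_a\tprotein_b\tscore\nA\tB\t699\nA\tC\t700\nB\tC\t701\n"
        )
        edges = read_interactome(f, 700)
        assert len(edges) == 2

    def test_reversed_duplicates_collapse(self, tmp_path):
        f = tmp_path / "ppi.tsv"
        f.write_text("protein_a\tprotein_b\tscore\nA\tB\t900\nB\tA\t900\nA\tA\t900\n")
        edges = read_interactome(f, 700)
        assert [(e[0], e[1]) for e in edges.edges] == [("A", "B")]

    def test_synthetic_file_matches_independent_recount(self, tmp_path, rng):
        names = [f"N{i}" for i in range(40)]
        rows = []
        for _ in range(500):
            a, b = rng.choice(len(names), 2)
            rows.append((names[a], names[b], int(rng.integers(0, 1000))))
        f = tmp_path / "ppi.tsv"
        f.write_text(
            "protein_a\tprotein_b\tscore\n"
            + "\n".join(f"{a}\t{b}\t{s}" for a, b, s in rows)
        )
        edges = read_interactome(f, 700)
        # independent filter-and-dedupe pass
        expected = set()
        for a, b, s in rows:
            if a != b and s >= 700 and (b, a) not in expected:
                expected.add((a, b))
        norm = {tuple(sorted(e)) for e in expected}
        assert {(a, b) for a, b, _ in edges.edges} == norm

    def test_non_integer_score_raises(self, tmp_path):
        f = tmp_path / "ppi.tsv"
        f.write_text("protein_a\tprotein_b\tscore\nA\tB\thigh\n")
        with pytest.raises(InputFormatError):
            read_interactome(f, 700)


class TestSummarize:
    def test_single_association_means_are_one(self):
        table = AssociationTable([AssociationRecord("P", "p", "G")])
        s = summarize_associations(table)
        assert s["mean_genes_per_phenotype_2dp"] == 1.00
        assert s["mean_phenotypes_per_gene_2dp"] == 1.00

    def test_mean_identity_holds(self, rng):
        records = [
            AssociationRecord(f"P{rng.integers(20)}", "l", f"G{rng.integers(40)}")
            for _ in range(200)
        ]
        table = AssociationTable(records)
        s = summarize_associations(table)
        assert s["n_associations"] == pytest.approx(
            s["mean_genes_per_phenotype"] * s["n_phenotypes"]
        )
        assert s["n_associations"] == pytest.approx(
            s["mean_phenotypes_per_gene"] * s["n_genes"]
        )
        assert sum(k * v for k, v in s["genes_per_phenotype_hist"].items()) == s[
            "n_associations"
        ]

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            summarize_associations(AssociationTable([]))


class TestRoundTrips:
    def test_associations(self, tmp_path):
        table = AssociationTable(
            [
                AssociationRecord("C1", "发热", "A", "T184"),
                AssociationRecord("C2", "rash", "B"),
            ]
        )
        p = tmp_path / "a.tsv"
        data_io.write_associations(table, p)
        assert data_io.read_associations(p) == table

    def test_term_mapping(self, tmp_path):
        m = TermMapping({"C1": "发热", "C2": "发热", "C3": "rash"})
        p = tmp_path / "m.tsv"
        data_io.write_term_mapping(m, p)
        assert data_io.read_term_mapping(p).entries == m.entries

    def test_interactome(self, tmp_path):
        e = InteractomeEdgeList([("A", "B", 900), ("B", "C", 702)])
        p = tmp_path / "e.tsv"
        data_io.write_interactome(e, p)
        assert data_io.read_interactome(p, 700).edges == e.edges

    def test_cluster_records(self, tmp_path):
        r = ClusterRecordSet(
            [frozenset({"a", "b"}), frozenset({"c"})], ["chief1", "chief2"]
        )
        p = tmp_path / "r.tsv"
        data_io.write_cluster_records(r, p)
        back = data_io.read_cluster_records(p)
        assert back.records == r.records
        assert back.chief == r.chief

    def test_drug_targets(self, tmp_path):
        t = DrugTargetTable({("D1", "G1"), ("D1", "G2"), ("D2", "G1")})
        p = tmp_path / "d.tsv"
        data_io.write_drug_targets(t, p)
        assert data_io.read_drug_targets(p).pairs == t.pairs

    def test_gene_sets(self, tmp_path):
        c = GeneSetCollection(
            {"PW1": ("desc one", frozenset({"A", "B"})), "PW2": ("d", frozenset({"B"}))}
        )
        p = tmp_path / "s.gmt"
        data_io.write_gene_sets(c, p)
        assert data_io.read_gene_sets(p) == c

    def test_category_annotation(self, tmp_path):
        ann = data_io.CategoryAnnotation({"fever": "GS", "rash": "SITS"})
        p = tmp_path / "c.tsv"
        data_io.write_category_annotation(ann, p)
        assert data_io.read_category_annotation(p).entries == ann.entries


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(37.2991, 2) == 37.30
    assert round_half_up(2.0 / 3.0 * 100, 2) == 66.67
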