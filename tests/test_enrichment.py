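from math import comb

import numpy as np
import pandas as pd
import pytest

from symdiv.data_io import GeneSetCollection
from symdiv.diversity import PairDiversity
from symdiv.enrichment import (
    cluster_pathway_matrix,
    enrich,
    overlap_enriched,
    select_case_pairs,
)


def hypergeom_tail_sum(k, N, m, n):
    """Independent oracle: exhaustive sum of the hypergeometric mass for X >= k."""
    total = 0.0
    for x in range(k, min(m, n) + 1):
        total += comb(m, x) * comb(N - m, n - x) / comb(N, n)
    return total


def collection_from(sets, universe=None):
    return GeneSetCollection(
        {name: ("", frozenset(genes)) for name, genes in sets.items()},
        frozenset(universe) if universe else None,
    )


class TestEnrich:
    def test_single_gene_closed_form(self):
        universe = {f"g{i}" for i in range(20)}
        coll = collection_from({"S": {"g0", "g1", "g2", "g3"}}, universe)
        res = enrich({"g0"}, coll, universe=universe)
        p = res.rows.loc[res.rows["set_name"] == "S", "p_value"].iloc[0]
        assert p == pytest.approx(4 / 20)

    def test_disjoint_query_p_is_one(self):
        universe = {f"g{i}" for i in range(10)}
        coll = collection_from({"S": {"g0", "g1"}}, universe)
        res = enrich({"g5", "g6"}, coll, universe=universe)
        assert res.rows["p_value"].iloc[0] == 1.0

    def test_matches_exhaustive_tail_sum(self, rng):
        universe = [f"g{i}" for i in range(60)]
        for _ in range(40):
            m = int(rng.integers(2, 25))
            members = set(rng.choice(universe, m, replace=False))
            coll = collection_from({"S": members}, universe)
            n = int(rng.integers(1, 20))
            query = set(rng.choice(universe, n, replace=False))
            res = enrich(query, coll, universe=universe)
            row = res.rows.iloc[0]
            expected = hypergeom_tail_sum(int(row["overlap"]), 60, m, n)
            assert row["p_value"] == pytest.approx(expected, abs=1e-10)

    def test_monotone_decreasing_in_overlap(self):
        universe = [f"g{i}" for i in range(30)]
        members = set(universe[:10])
        coll = collection_from({"S": members}, universe)
        ps = []
        for k in range(1, 6):
            query = set(universe[:k]) | set(universe[20 : 25 - k + 1])
            res = enrich(query, coll, universe=universe)
            row = res.rows.iloc[0]
            ps.append((int(row["overlap"]), row["p_value"]))
        ps.sort()
        pvals = [p for _, p in ps]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_gene_order_invariance(self, rng):
        universe = [f"g{i}" for i in range(40)]
        coll = collection_from({"S": set(universe[:12])}, universe)
        q = list(rng.choice(universe, 10, replace=False))
        p1 = enrich(q, coll, universe=universe).rows["p_value"].iloc[0]
        p2 = enrich(reversed(q), coll, universe=universe).rows["p_value"].iloc[0]
        assert p1 == p2

    def test_query_outside_universe_raises(self):
        coll = collection_from({"S": {"a", "b"}})
        with pytest.raises(ValueError):
            enrich({"zzz"}, coll)

    def test_universe_must_cover_sets(self):
        coll = collection_from({"S": {"a", "b"}})
        with pytest.raises(ValueError):
            enrich({"a"}, coll, universe={"a"})

    def test_bh_correction_flag(self, rng):
        universe = [f"g{i}" for i in range(50)]
        sets = {f"S{i}": set(rng.choice(universe, 8, replace=False)) for i in range(6)}
        coll = collection_from(sets, universe)
        res = enrich(set(universe[:10]), coll, universe=universe, correct=True)
        assert "p_adjusted" in res.rows.columns
        assert (res.rows["p_adjusted"] >= res.rows["p_value"] - 1e-15).all()


class TestOverlap:
    def _result(self, coll, genes, label):
        return enrich(genes, coll, p_threshold=0.5, query_label=label)

    def test_identical_results_full_overlap(self):
        universe = [f"g{i}" for i in range(30)]
        coll = collection_from(
            {"A": set(universe[:5]), "B": set(universe[5:10])}, universe
        )
        r = self._result(coll, set(universe[:5]), "x")
        ov = overlap_enriched(r, r)
        assert ov.overlapped == r.enriched_names()
        assert ov.n_overlap == ov.n_total

    def test_disjoint_enrichment_no_overlap(self):
        universe = [f"g{i}" for i in range(30)]
        coll = collection_from(
            {"A": set(universe[:5]), "B": set(universe[10:15])}, universe
        )
        ra = self._result(coll, set(universe[:5]), "x")
        rb = self._result(coll, set(universe[10:15]), "y")
        ov = overlap_enriched(ra, rb)
        assert ov.n_overlap == 0

    def test_overlap_is_name_intersection(self, rng):
        universe = [f"g{i}" for i in range(50)]
        coll = collection_from(
            {f"S{i}": set(rng.choice(universe, 10, replace=False)) for i in range(8)},
            universe,
        )
        ra = self._result(coll, set(rng.choice(universe, 15, replace=False)), "a")
        rb = self._result(coll, set(rng.choice(universe, 15, replace=False)), "b")
        ov = overlap_enriched(ra, rb)
        assert ov.overlapped == ra.enriched_names() & rb.enriched_names()
        assert ov.n_total == len(ra.enriched_names())

    def test_collection_mismatch_raises(self):
        universe = ["a", "b", "c"]
        c1 = collection_from({"S": {"a"}}, universe)
        c2 = collection_from({"S": {"a"}}, universe)
        with pytest.raises(ValueError):
            overlap_enriched(
                enrich({"a"}, c1, query_label="x"), enrich({"a"}, c2, query_label="y")
            )


class TestCasePairs:
    def _pair(self, w):
        return PairDiversity(("a", f"b{w}"), frozenset({"g"}), 1.0, 1, "g", w)

    def test_inclusive_threshold(self):
        pairs = [self._pair(14), self._pair(15), self._pair(16)]
        assert len(select_case_pairs(pairs, 15)) == 2

    def test_zero_threshold_keeps_all_sorted(self):
        pairs = [self._pair(3), self._pair(9), self._pair(1)]
        out = select_case_pairs(pairs, 0)
        assert [p.cooccurrence_weight for p in out] == [9, 3, 1]


class TestClustering:
    def test_duplicate_rows_co_clustered(self):
        mat = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]],
            index=["r1", "r2", "r3"],
            columns=list("abcd"),
        )
        res = cluster_pathway_matrix(mat, n_clusters=2)
        assert res.row_labels["r1"] == res.row_labels["r2"]
        assert res.row_labels["r1"] != res.row_labels["r3"]

    def test_identity_matrix_each_row_own_cluster(self):
        mat = pd.DataFrame(np.eye(4, dtype=int), index=list("wxyz"))
        res = cluster_pathway_matrix(mat, n_clusters=4)
        assert len(set(res.row_labels.values())) == 4

    def test_single_row_trivial_cluster(self):
        mat = pd.DataFrame([[1, 0, 1]], index=["only"])
        res = cluster_pathway_matrix(mat, n_clusters=1)
        assert res.row_labels == {"only": 1}

    def test_planted_two_block_recovery(self, rng):
        # two blocks of rows using disjoint pathway sets, 5% bit flips
        n_rows, n_cols = 40, 30
        truth = np.array([0] * 20 + [1] * 20)
        X = np.zeros((n_rows, n_cols), dtype=int)
        X[:20, :15] = 1
        X[20:, 15:] = 1
        flips = rng.random(X.shape) < 0.05
        X = np.where(flips, 1 - X, X)
        mat = pd.DataFrame(X, index=[f"r{i}" for i in range(n_rows)])
        res = cluster_pathway_matrix(mat, n_clusters=2)
        labels = np.array([res.row_labels[f"r{i}"] for i in range(n_rows)])
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) > 0.9

    def test_invariant_under_row_permutation(self, rng):
        X = (rng.random((12, 8)) < 0.4).astype(int)
        X[0] = 1  # avoid all-zero rows with undefined jaccard distance
        mat = pd.DataFrame(X, index=[f"r{i}" for i in range(12)])
        perm = rng.permutation(12)
        shuffled = mat.iloc[perm]
        a = cluster_pathway_matrix(mat, n_clusters=3).row_labels
        b = cluster_pathway_matrix(shuffled, n_clusters=3).row_labels
        # same partition up to relabeling
        from sklearn.metrics import adjusted_rand_score

        keys = sorted(a)
        assert (
            adjusted_rand_score([a[k] for k in keys], [b[k] for k in keys]) == 1.0
        )

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            cluster_pathway_matrix(pd.DataFrame())
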