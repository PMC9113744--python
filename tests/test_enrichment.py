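import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import thermatlas as ta
from thermatlas.io_formats import GeneSet, GeneSetCollection
from thermatlas.enrichment import (
    EnrichmentTable,
    aggregate_term_counts,
    classify_terms,
    enrich_all,
    fisher_ora,
    rank_terms,
    venn_decomposition,
)


def hypergeom_tail_oracle(k, M, K, n):
    """Upper-tail hypergeometric probability by exact-rational enumeration."""
    total = math.comb(M, n)
    num = sum(
        math.comb(K, j) * math.comb(M - K, n - j)
        for j in range(k, min(K, n) + 1)
    )
    return Fraction(num, total)


class TestFisherOra:
    def test_disjoint_set_gives_p_one(self):
        p, ratio, overlap = fisher_ora({"a", "b"}, {"a", "b", "c", "d"}, {"c", "d"})
        assert p == 1.0
        assert overlap == []

    def test_known_configuration_matches_enumeration(self):
        universe = [f"g{i}" for i in range(20)]
        de = universe[:5]
        gene_set = universe[2:8]  # 6 members, overlap with DE = 3
        p, ratio, overlap = fisher_ora(de, universe, gene_set)
        k = len(set(de) & set(gene_set))
        oracle = float(hypergeom_tail_oracle(k, 20, 6, 5))
        assert p == pytest.approx(oracle, rel=1e-12)
        assert ratio == k / 6

    def test_de_equals_universe_forces_p_one(self):
        u = {"a", "b", "c"}
        p, ratio, overlap = fisher_ora(u, u, {"a", "b"})
        assert p == pytest.approx(1.0)

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError, match="empty universe"):
            fisher_ora(set(), set(), {"a"})

    def test_set_outside_universe_gives_p_one_zero_ratio(self):
        p, ratio, overlap = fisher_ora({"a"}, {"a", "b"}, {"zz"})
        assert (p, ratio, overlap) == (1.0, 0.0, [])

    def test_monotone_in_overlap_at_fixed_margins(self):
        # enlarging overlap (fixed |universe|, |set|, |DE|) never increases p
        M, K, n = 40, 10, 12
        universe = [f"g{i}" for i in range(M)]
        ps = []
        for k in range(0, min(K, n) + 1):
            de = universe[:k] + universe[K : K + (n - k)]
            p, _, _ = fisher_ora(de, universe, universe[:K])
            ps.append(p)
        assert all(b <= a + 1e-15 for a, b in zip(ps, ps[1:]))


def build_enrichment(rows, p_select=0.01, temp=None):
    return EnrichmentTable(
        pd.DataFrame(
            rows,
            columns=[
                "tissue", "direction", "term_id", "term_name", "p_value",
                "n_de_in_set", "n_universe_in_set", "gene_ratio", "genes",
            ],
        ),
        p_select,
        temp,
    )


class TestEnrichAll:
    def test_planted_set_retained_in_right_direction(self, make_det):
        genes = [f"g{i}" for i in range(100)]
        calls = {}
        for i, g in enumerate(genes):
            if i < 16:
                calls[g] = (2.0, 0.001, "up")
            else:
                calls[g] = (0.0, 0.9, "ns")
        cs = ta.ContrastSet()
        cs.add(make_det(calls, tissue="A"))
        coll = GeneSetCollection(
            {
                "T1": GeneSet("T1", "planted", tuple(genes[:20])),  # 80% DE-up
                "T2": GeneSet("T2", "background", tuple(genes[50:70])),
            }
        )
        enr = enrich_all(cs, coll, p_select=0.01)
        hits = enr.table[["tissue", "direction", "term_id"]].itertuples(index=False)
        assert ("A", "up", "T1") in [tuple(h) for h in hits]
        assert "T2" not in set(enr.table["term_id"])

    def test_retention_matches_brute_force_thresholding(self, make_det):
        rng = np.random.default_rng(23)
        genes = [f"g{i}" for i in range(60)]
        calls = {}
        for g in genes:
            u = rng.random()
            if u < 0.2:
                calls[g] = (1.0, 0.01, "up")
            elif u < 0.4:
                calls[g] = (-1.0, 0.01, "down")
            else:
                calls[g] = (0.0, 0.9, "ns")
        cs = ta.ContrastSet()
        cs.add(make_det(calls, tissue="A"))
        sets = {
            f"T{j}": GeneSet(
                f"T{j}", "", tuple(rng.choice(genes, size=12, replace=False))
            )
            for j in range(8)
        }
        coll = GeneSetCollection(sets)
        enr = enrich_all(cs, coll, p_select=0.05)
        det = next(iter(cs))
        universe = set(det.tested_genes())
        for direction in ("up", "down"):
            de = set(det.genes_called(direction))
            for tid, s in sets.items():
                p, _, _ = fisher_ora(de, universe, s.genes)
                retained = (
                    (enr.table["term_id"] == tid)
                    & (enr.table["direction"] == direction)
                ).any()
                assert retained == (p < 0.05)

    def test_term_counts_aggregation(self):
        counts = pd.DataFrame(
            {"tissue": ["a", "b"], "n_up_terms": [3, 4], "n_down_terms": [1, 0]}
        )
        totals = aggregate_term_counts(counts)
        assert totals == {"n_up_terms": 7, "n_down_terms": 1}


class TestRankTerms:
    def test_tie_broken_by_gene_ratio(self):
        enr = build_enrichment(
            [
                ("A", "up", "T1", "", 0.001, 2, 10, 0.2, "a;b"),
                ("A", "up", "T2", "", 0.001, 5, 10, 0.5, "a;b;c;d;e"),
            ]
        )
        ranked = rank_terms(enr, top_n=50)
        assert list(ranked["term_id"]) == ["T2", "T1"]

    def test_fewer_terms_than_top_n_returns_all(self):
        enr = build_enrichment([("A", "up", "T1", "", 0.001, 2, 10, 0.2, "a;b")])
        assert len(rank_terms(enr, top_n=50)) == 1

    def test_order_matches_brute_force_sort(self):
        rng = np.random.default_rng(29)
        rows = [
            ("A", "up", f"T{j}", "", float(rng.choice([1e-4, 1e-3])),
             2, 10, float(rng.choice([0.2, 0.5, 0.8])), "x")
            for j in range(12)
        ]
        enr = build_enrichment(rows)
        ranked = rank_terms(enr, top_n=12)
        expect = sorted(rows, key=lambda r: (r[4], -r[7], r[2]))
        assert list(ranked["term_id"]) == [r[2] for r in expect]


class TestClassifyTerms:
    def test_cold_up_warm_down_is_cross_condition_opposite(self):
        cold = build_enrichment([("A", "up", "T1", "", 1e-3, 3, 5, 0.6, "a;b;c")])
        warm = build_enrichment([("A", "down", "T1", "", 1e-3, 3, 5, 0.6, "a;b;c")])
        cls = classify_terms(cold, warm)
        assert cls.loc["T1", "cls"] == "cross_condition_opposite"

    def test_single_hit_is_tissue_specific(self):
        cold = build_enrichment([("A", "up", "T1", "", 1e-3, 3, 5, 0.6, "a")])
        warm = build_enrichment([])
        cls = classify_terms(cold, warm)
        assert cls.loc["T1", "cls"] == "tissue_specific"

    def test_precedence_and_exhaustiveness_on_random_profiles(self):
        rng = np.random.default_rng(31)
        tissues = ["A", "B", "C"]
        rows_cold, rows_warm = [], []
        for j in range(40):
            for t in tissues:
                for direction in ("up", "down"):
                    if rng.random() < 0.25:
                        rows_cold.append(
                            (t, direction, f"T{j}", "", 1e-3, 2, 5, 0.4, "g")
                        )
                    if rng.random() < 0.25:
                        rows_warm.append(
                            (t, direction, f"T{j}", "", 1e-3, 2, 5, 0.4, "g")
                        )
        cold, warm = build_enrichment(rows_cold), build_enrichment(rows_warm)
        cls = classify_terms(cold, warm)
        # brute-force set logic per term
        cold_df, warm_df = cold.table, warm.table
        for term, row in cls.iterrows():
            c = cold_df[cold_df.term_id == term]
            w = warm_df[warm_df.term_id == term]
            cu = set(c[c.direction == "up"].tissue)
            cd = set(c[c.direction == "down"].tissue)
            wu = set(w[w.direction == "up"].tissue)
            wd = set(w[w.direction == "down"].tissue)
            if (cu or cd) and (wu or wd):
                expect = (
                    "cross_condition_opposite"
                    if (cu and wd) or (cd and wu)
                    else "cross_condition_same"
                )
            else:
                u, d = (cu, cd) if (cu or cd) else (wu, wd)
                if len(u) + len(d) == 1:
                    expect = "tissue_specific"
                elif u and d:
                    expect = "shared_mixed"
                else:
                    expect = "shared_same_direction"
            assert row["cls"] == expect
        assert set(cls["cls"]) <= set(
            [
                "cross_condition_opposite", "cross_condition_same",
                "shared_mixed", "shared_same_direction", "tissue_specific",
            ]
        )


class TestVennDecomposition:
    def enrichment_with_drivers(self, drivers):
        rows = [
            (t, "up", "T1", "", 1e-3, len(gs), 10, 0.5, ";".join(sorted(gs)))
            for t, gs in drivers.items()
        ]
        return build_enrichment(rows)

    def test_worked_example(self):
        enr = self.enrichment_with_drivers(
            {"X": {"A", "B", "C", "D"}, "Y": {"A", "E"}, "Z": {"A", "F"}}
        )
        comp = venn_decomposition("T1", enr, ["X", "Y", "Z"])
        assert comp[("X", "Y", "Z")] == ["A"]
        assert comp[("X", "Y")] == [] and comp[("X", "Z")] == [] and comp[("Y", "Z")] == []
        assert comp[("X",)] == ["B", "C", "D"]
        assert comp[("Y",)] == ["E"]
        assert comp[("Z",)] == ["F"]

    def test_identical_sets_all_in_center(self):
        enr = self.enrichment_with_drivers({"X": {"a", "b"}, "Y": {"a", "b"}})
        comp = venn_decomposition("T1", enr, ["X", "Y"])
        assert comp[("X", "Y")] == ["a", "b"]
        assert comp[("X",)] == [] and comp[("Y",)] == []

    def test_disjoint_drivers_empty_center(self):
        enr = self.enrichment_with_drivers(
            {"X": {"a"}, "Y": {"b"}, "Z": {"c"}}
        )
        comp = venn_decomposition("T1", enr, ["X", "Y", "Z"])
        assert comp[("X", "Y", "Z")] == []
        assert comp[("X",)] == ["a"]

    def test_partition_property_on_random_sets(self):
        rng = np.random.default_rng(37)
        pool = [f"g{i}" for i in range(30)]
        for _ in range(20):
            drivers = {
                t: set(rng.choice(pool, size=rng.integers(1, 12), replace=False))
                for t in ("X", "Y", "Z")
            }
            enr = self.enrichment_with_drivers(drivers)
            comp = venn_decomposition("T1", enr, ["X", "Y", "Z"])
            all_genes = sorted(set().union(*drivers.values()))
            flattened = sorted(g for genes in comp.values() for g in genes)
            assert flattened == all_genes  # disjoint and covering

    def test_term_in_fewer_than_two_tissues_is_error(self):
        enr = self.enrichment_with_drivers({"X": {"a"}})
        with pytest.raises(ValueError, match="T1"):
            venn_decomposition("T1", enr, ["X", "Y"])
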