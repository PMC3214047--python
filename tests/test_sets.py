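"""Gene-level set algebra and hypergeometric category enrichment."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import chiptile as ct
from chiptile.io_formats import GeneSet

symbols_st = st.sets(st.text(alphabet="abcdefgh", min_size=1, max_size=3), max_size=30)


class TestVenn:
    def test_hand_enumeration(self):
        a = GeneSet("A", ["a", "b", "c"])
        b = GeneSet("B", ["b", "c", "d"])
        c = GeneSet("C", ["c"])
        v = ct.venn([a, b, c])
        assert v.count("A", "B", "C") == 1
        assert v.common.symbols == ["c"]
        assert v.count("A") == 1 and v.count("B") == 1  # {a}; {d}
        assert v.count("A", "B") == 1  # {b}
        assert v.count("C") == 0

    def test_identical_sets(self):
        a = GeneSet("A", ["x", "y"])
        b = GeneSet("B", ["x", "y"])
        v = ct.venn([a, b])
        assert v.count("A", "B") == 2
        assert v.count("A") == v.count("B") == 0

    def test_case_insensitive_matching(self):
        v = ct.venn([GeneSet("A", ["Tap1"]), GeneSet("B", ["TAP1"])])
        assert v.count("A", "B") == 1

    def test_wrong_arity(self):
        with pytest.raises(ValueError):
            ct.venn([GeneSet("A", ["a"])])

    @given(symbols_st, symbols_st, symbols_st)
    def test_inclusion_exclusion(self, sa, sb, sc):
        a, b, c = GeneSet("A", sa), GeneSet("B", sb), GeneSet("C", sc)
        v = ct.venn([a, b, c])
        assert v.union_size == len(sa | sb | sc)
        # inclusion-exclusion: |A| equals the sum of regions containing A
        for name, s in (("A", sa), ("B", sb), ("C", sc)):
            total = sum(cnt for key, cnt in v.region_counts.items() if name in key)
            assert total == len(s)

    def test_random_triples_match_brute_force(self):
        rng = np.random.default_rng(1)
        pool = [f"g{i}" for i in range(800)]
        for _ in range(20):
            picks = [set(rng.choice(pool, 500, replace=False)) for _ in range(3)]
            v = ct.venn([GeneSet(n, p) for n, p in zip("ABC", picks)])
            for key, cnt in v.region_counts.items():
                expected = len(
                    set.intersection(*(picks["ABC".index(n)] for n in key))
                    - set().union(*(picks["ABC".index(n)] for n in "ABC" if n not in key))
                ) if len(key) < 3 else len(set.intersection(*picks))
                assert cnt == expected


class TestSetOps:
    def test_subtract(self):
        out = ct.subtract_control(GeneSet("t", ["a", "b"]), GeneSet("c", ["B"]))
        assert out.symbols == ["a"]

    def test_subtract_disjoint_identity(self):
        t = GeneSet("t", ["a", "b"])
        assert ct.subtract_control(t, GeneSet("c", ["x"])) == t

    def test_subtract_superset_empty(self):
        assert len(ct.subtract_control(GeneSet("t", ["a"]), GeneSet("c", ["a", "b"]))) == 0

    @pytest.mark.parametrize(
        "query,ref,expected",
        [
            (list("abcdefghij"), ["a", "b", "c"], 30.0),
            (["a", "b"], ["x"], 0.0),
            (["a", "b"], ["a", "b", "c"], 100.0),
        ],
    )
    def test_overlap_fraction(self, query, ref, expected):
        assert ct.overlap_fraction(GeneSet("q", query), GeneSet("r", ref)) == expected

    def test_overlap_empty_query(self):
        with pytest.raises(ValueError):
            ct.overlap_fraction(GeneSet("q", []), GeneSet("r", ["a"]))

    def test_partition(self):
        both, only = ct.partition_by_cobinding(
            GeneSet("p", ["a", "b", "c"]), GeneSet("c", ["b", "c", "d"])
        )
        assert both.symbols == ["b", "c"]
        assert only.symbols == ["a"]

    def test_partition_empty_cofactor(self):
        p = GeneSet("p", ["a", "b"])
        both, only = ct.partition_by_cobinding(p, GeneSet("c", []))
        assert len(both) == 0 and only.keys == p.keys

    @given(symbols_st, symbols_st)
    def test_partition_sizes_sum(self, sp, sc):
        p = GeneSet("p", sp)
        both, only = ct.partition_by_cobinding(p, GeneSet("c", sc))
        assert len(both) + len(only) == len(p)
        assert both.keys | only.keys == p.keys
        assert not (both.keys & only.keys)


class TestOrthologs:
    def test_case_insensitive_fallback(self):
        out = ct.map_orthologs(GeneSet("m", ["Tap1", "Btk"]), GeneSet("h", ["TAP1", "CD74"]))
        assert out.symbols == ["Tap1"]

    def test_explicit_table(self):
        out = ct.map_orthologs(GeneSet("a", ["Xa"]), GeneSet("b", ["YB"]),
                               ortholog_table=[("Xa", "YB")])
        assert out.symbols == ["Xa"]

    def test_empty_table_disjoint(self):
        out = ct.map_orthologs(GeneSet("a", ["Xa"]), GeneSet("b", ["YB"]),
                               ortholog_table=[])
        assert len(out) == 0

    def test_one_to_many(self):
        table = [("Xa", "Y1"), ("Xa", "Y2")]
        out = ct.map_orthologs(GeneSet("a", ["Xa"]), GeneSet("b", ["Y2"]), table)
        assert out.symbols == ["Xa"]


class TestCategoryEnrichment:
    def test_exact_hypergeometric_value(self):
        universe = GeneSet("u", [f"g{i}" for i in range(10)])
        category = GeneSet("cat", [f"g{i}" for i in range(5)])
        query = GeneSet("q", [f"g{i}" for i in range(5)])
        (res,) = ct.category_enrichment(query, {"cat": category}, universe)
        # C(5,5)*C(5,0)/C(10,5) = 1/252
        assert res.p_value == pytest.approx(1 / 252, rel=1e-9)

    def test_expected_overlap_not_significant(self):
        universe = GeneSet("u", [f"g{i}" for i in range(20)])
        category = GeneSet("cat", [f"g{i}" for i in range(10)])  # K=10, N=20
        query = GeneSet("q", [f"g{i}" for i in (0, 1, 2, 3, 4, 10, 11, 12, 13, 14)])
        (res,) = ct.category_enrichment(query, {"cat": category}, universe)
        assert res.overlap == 5  # == n*K/N
        assert res.p_value > 0.05

    def test_p_monotone_in_overlap(self):
        from scipy.stats import hypergeom
        ps = [hypergeom.sf(k - 1, 100, 20, 30) for k in range(0, 21)]
        assert ps == sorted(ps, reverse=True)
        # and through the package surface:
        universe = GeneSet("u", [f"g{i}" for i in range(40)])
        cat = GeneSet("cat", [f"g{i}" for i in range(10)])
        p_prev = 1.1
        for k in (2, 5, 8):
            query = GeneSet("q", [f"g{i}" for i in range(k)] +
                            [f"g{i}" for i in range(20, 30 - k + 10)])
            (res,) = ct.category_enrichment(query, {"cat": cat}, universe)
            assert res.p_value < p_prev
            p_prev = res.p_value

    def test_null_pvalues_approximately_uniform(self):
        """Random queries from the universe give ~uniform enrichment p-values."""
        from scipy import stats
        rng = np.random.default_rng(2)
        pool = [f"g{i}" for i in range(2000)]
        universe = GeneSet("u", pool)
        cat = GeneSet("cat", pool[:500])
        pvals = []
        for _ in range(200):
            q = GeneSet("q", rng.choice(pool, 300, replace=False))
            (res,) = ct.category_enrichment(q, {"cat": cat}, universe)
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_outside_universe_dropped_with_warning(self, caplog):
        universe = GeneSet("u", ["a", "b", "c", "d"])
        query = GeneSet("q", ["a", "zz"])
        with caplog.at_level("WARNING"):
            (res,) = ct.category_enrichment(query, {"cat": GeneSet("cat", ["a"])}, universe)
        assert res.query_size == 1
        assert "dropped" in caplog.text

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ct.category_enrichment(GeneSet("q", ["a"]), {}, GeneSet("u", []))

    def test_bh_adjustment_across_categories(self):
        universe = GeneSet("u", [f"g{i}" for i in range(100)])
        cats = {f"c{j}": GeneSet(f"c{j}", [f"g{i}" for i in range(j * 10, j * 10 + 10)])
                for j in range(5)}
        query = GeneSet("q", [f"g{i}" for i in range(10)])
        results = ct.category_enrichment(query, cats, universe)
        assert all(r.q_value >= r.p_value for r in results)
        assert [r.p_value for r in results] == sorted(r.p_value for r in results)
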