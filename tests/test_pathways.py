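"""Deciles, competitive tests, Fisher scans and step-wise refinement."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from devassoc.pathways import (
    CompetitiveGeneSetTest,
    TermCollection,
    competitive_decile_test,
    conditional_term_association,
    decile_bins,
    decile_scan,
    fisher_term_scan,
    merge_significant_deciles,
    refine_terms,
)


def _assoc(z, ids=None):
    n = len(z)
    ids = ids if ids is not None else [f"g{i:04d}" for i in range(n)]
    size = np.full(n, 50_000.0)
    k = np.full(n, 10.0)
    return pd.DataFrame(
        {
            "gene_id": ids,
            "z": z,
            "size": size,
            "density": k / size,
            "log_size": np.log(size),
            "log_density": np.log(k / size),
        }
    )


def _terms(membership):
    rows = [
        (tid, tid.split(":")[0], tid, g, "EXP")
        for tid, members in membership.items()
        for g in members
    ]
    return TermCollection(
        pd.DataFrame(rows, columns=["term_id", "source", "name", "gene_id", "evidence"])
    )


def hypergeom_greater(a, b, c, d):
    """Independent oracle: exhaustive one-sided Fisher p by enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    p = 0
    for x in range(a, min(r1, c1) + 1):
        p += math.comb(r1, x) * math.comb(r2, c1 - x)
    return p / denom


class TestDecileBins:
    def test_hundred_distinct_scores(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.permutation(100).astype(float), index=[f"g{i:03d}" for i in range(100)])
        d = decile_bins(s)
        assert d.value_counts().eq(10).all()
        top = set(d.index[d == 10])
        assert top == set(s.nlargest(10).index)

    def test_uneven_split_differs_by_at_most_one(self):
        s = pd.Series(np.arange(101.0), index=[f"g{i:03d}" for i in range(101)])
        counts = decile_bins(s).value_counts()
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == 101

    def test_all_ties_deterministic_by_gene_id(self):
        ids = [f"g{i:03d}" for i in range(40)]
        s1 = pd.Series(1.0, index=ids)
        s2 = pd.Series(1.0, index=list(reversed(ids)))
        pd.testing.assert_series_equal(decile_bins(s1), decile_bins(s2))

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.standard_normal(73), index=[f"g{i:03d}" for i in range(73)])
        d = decile_bins(s)
        assert len(d) == 73 and d.index.is_unique
        assert set(d.unique()) <= set(range(1, 11))

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            decile_bins(pd.Series([1.0] * 9, index=[f"g{i}" for i in range(9)]))


class TestCompetitiveTest:
    def test_complement_negates_beta_same_p(self):
        rng = np.random.default_rng(2)
        assoc = _assoc(rng.standard_normal(100))
        members = set(assoc["gene_id"][:30])
        rest = set(assoc["gene_id"]) - members
        r1 = competitive_decile_test(assoc, members)
        r2 = competitive_decile_test(assoc, rest)
        assert r2.effect == pytest.approx(-r1.effect, rel=1e-9)
        assert r2.p == pytest.approx(r1.p, rel=1e-9)

    def test_whole_universe_rejected(self):
        assoc = _assoc(np.random.default_rng(3).standard_normal(20))
        with pytest.raises(ValueError, match="whole universe"):
            competitive_decile_test(assoc, set(assoc["gene_id"]))
        with pytest.raises(ValueError, match="intersect"):
            competitive_decile_test(assoc, {"absent"})

    def test_planted_shift_detected_with_direction(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(400)
        z[:40] += 1.0
        assoc = _assoc(z)
        res = competitive_decile_test(assoc, set(assoc["gene_id"][:40]))
        assert res.effect > 0 and res.direction == 1
        assert res.p_adj < 0.05
        assert res.p_adj == pytest.approx(min(1.0, res.p * 10))


class TestMergeDeciles:
    def test_union_of_same_direction_significant(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal(300)
        ids = [f"g{i:04d}" for i in range(300)]
        s = pd.Series(np.arange(300.0), index=ids)
        z[np.argsort(s.to_numpy())[-60:]] += 1.2  # top two deciles shifted
        assoc = _assoc(z, ids=ids)
        d = decile_bins(s)
        scan = decile_scan(assoc, d)
        merged = merge_significant_deciles(scan, d)
        assert merged  # top deciles merged
        assert merged == set(d.index[d.isin({b for b in (9, 10) if f"decile_{b}" in {r.unit for r in scan if r.p_adj < 0.05}})]) or merged <= set(d.index)
        # merged deciles are disjoint bins: size is the sum of bin sizes
        bins = {int(r.unit.rsplit("_", 1)[1]) for r in scan if r.p_adj < 0.05 and r.direction == 1}
        assert len(merged) == int(d.isin(bins).sum())

    def test_no_significant_deciles_empty(self):
        rng = np.random.default_rng(6)
        ids = [f"g{i:04d}" for i in range(200)]
        assoc = _assoc(rng.standard_normal(200), ids=ids)
        d = decile_bins(pd.Series(rng.standard_normal(200), index=ids))
        scan = decile_scan(assoc, d)
        for r in scan:
            r.p_adj = 1.0
        assert merge_significant_deciles(scan, d) == set()


class TestFisher:
    def test_worked_table(self):
        terms = _terms({"GO:1": ["a", "b", "c", "e"]})
        background = set("abcdefgh")
        set_genes = set("abcd")
        out = fisher_term_scan(set_genes, terms, background)
        # table a=3, b=1, c=1, d=3
        assert out[0].extra["table"] == (3, 1, 1, 3)
        assert out[0].p == pytest.approx(0.242857142857, abs=1e-9)
        assert out[0].p == pytest.approx(hypergeom_greater(3, 1, 1, 3), abs=1e-12)

    def test_identical_and_disjoint_terms(self):
        background = {f"g{i}" for i in range(40)}
        set_genes = {f"g{i}" for i in range(10)}
        terms = _terms({"GO:same": sorted(set_genes), "GO:disjoint": [f"g{i}" for i in range(20, 30)]})
        out = {r.unit: r for r in fisher_term_scan(set_genes, terms, background)}
        assert out["GO:disjoint"].p == pytest.approx(1.0)
        # identical membership achieves the minimal possible p for the margins
        assert out["GO:same"].p == pytest.approx(1 / math.comb(40, 10), rel=1e-9)

    def test_enumeration_agreement_small_grid(self):
        for a in range(0, 5):
            for b in range(0, 5):
                for c in range(0, 5):
                    for d in range(0, 5):
                        if a + b == 0 or c + d == 0 or a + c == 0:
                            continue
                        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
                        assert p == pytest.approx(hypergeom_greater(a, b, c, d), abs=1e-12)

    def test_sources_corrected_separately(self):
        background = {f"g{i}" for i in range(30)}
        set_genes = {f"g{i}" for i in range(8)}
        terms = _terms({"GO:1": ["g0", "g1"], "GO:2": ["g2", "g3"], "MP:1": ["g4", "g5"]})
        out = fisher_term_scan(set_genes, terms, background)
        ms = {r.extra["source"]: r.extra["m"] for r in out}
        assert ms == {"GO": 2, "MP": 1}


class TestRefinement:
    def test_identical_terms_drop_later_one(self):
        background = {f"g{i}" for i in range(50)}
        set_genes = {f"g{i}" for i in range(12)}
        members = [f"g{i}" for i in range(10)]
        terms = _terms({"GO:aaa": members, "GO:bbb": members})
        sig = fisher_term_scan(set_genes, terms, background)
        refined, audit = refine_terms(sig, terms, set_genes, background)
        assert [r.unit for r in refined] == ["GO:aaa"]
        assert any(e["dropped"] for e in audit)

    def test_disjoint_terms_all_survive(self):
        background = {f"g{i}" for i in range(60)}
        set_genes = {f"g{i}" for i in range(20)}
        terms = _terms(
            {"GO:a": [f"g{i}" for i in range(8)], "GO:b": [f"g{i}" for i in range(10, 19)]}
        )
        sig = fisher_term_scan(set_genes, terms, background)
        refined, _ = refine_terms(sig, terms, set_genes, background)
        assert {r.unit for r in refined} == {"GO:a", "GO:b"}

    def test_nested_terms_large_dropped_when_signal_is_small_one(self):
        """small ⊂ large; all of the large term's in-set genes belong to the
        small term, so removing the small term leaves the large term empty of
        signal. Verified against direct Fisher recomputation."""
        background = {f"g{i}" for i in range(200)}
        set_genes = {f"g{i}" for i in range(30)}
        small = [f"g{i}" for i in range(12)]  # all in the set
        large = small + [f"g{i}" for i in range(150, 178)]  # adds only out-of-set genes
        terms = _terms({"GO:small": small, "GO:large": large})
        sig = fisher_term_scan(set_genes, terms, background)
        assert all(r.p_adj < 0.05 for r in sig)
        refined, audit = refine_terms(sig, terms, set_genes, background)
        assert [r.unit for r in refined] == ["GO:small"]
        # direct recomputation of the re-test table after removing `small`
        bg2 = background - set(small)
        sg2 = set_genes - set(small)
        members2 = set(large) & bg2
        a = len(members2 & sg2)
        _, p_re = stats.fisher_exact(
            [[a, len(sg2) - a], [len(members2) - a, len(bg2) - len(sg2) - (len(members2) - a)]],
            alternative="greater",
        )
        entry = [e for e in audit if e["retested_term"] == "GO:large"][0]
        assert entry["retest_p"] == pytest.approx(p_re, abs=1e-12)
        assert entry["dropped"]

    def test_order_invariance_for_distinct_sizes(self):
        background = {f"g{i}" for i in range(100)}
        set_genes = {f"g{i}" for i in range(25)}
        membership = {
            "GO:t1": [f"g{i}" for i in range(6)],
            "GO:t2": [f"g{i}" for i in range(10, 18)],
            "GO:t3": [f"g{i}" for i in range(3, 15)],
        }
        terms = _terms(membership)
        sig = fisher_term_scan(set_genes, terms, background)
        ref1, _ = refine_terms(list(sig), terms, set_genes, background)
        ref2, _ = refine_terms(list(reversed(sig)), terms, set_genes, background)
        assert [r.unit for r in ref1] == [r.unit for r in ref2]


class TestConditionalTermAssociation:
    def _setup(self, shift):
        rng = np.random.default_rng(9)
        n = 400
        ids = [f"g{i:04d}" for i in range(n)]
        z = rng.standard_normal(n)
        decile = set(ids[:80])
        term = set(ids[:20])
        z[:20] += shift
        return _assoc(z, ids=ids), term, decile

    def test_one_tailed_direction_logic(self):
        assoc, term, decile = self._setup(+1.2)
        up = conditional_term_association(assoc, term, decile, direction="greater")
        down = conditional_term_association(assoc, term, decile, direction="less")
        assert up.p < 0.05 and down.p > 0.5

    def test_negative_shift_detected_as_lower(self):
        assoc, term, decile = self._setup(-1.2)
        down = conditional_term_association(assoc, term, decile, direction="less")
        up = conditional_term_association(assoc, term, decile, direction="greater")
        assert down.p < 0.05 and up.p > 0.5

    def test_empty_overlap_skipped(self):
        assoc, term, decile = self._setup(0.0)
        assert conditional_term_association(assoc, set(), decile) is None

    def test_estimator_one_tailed_matches_two_tailed_relation(self):
        rng = np.random.default_rng(10)
        assoc = _assoc(rng.standard_normal(100))
        X = assoc.set_index("gene_id")[["size", "density", "log_size", "log_density"]]
        est = CompetitiveGeneSetTest(alternative="greater").fit(
            X, assoc["z"].to_numpy(), gene_set=set(assoc["gene_id"][:25])
        )
        if est.t_ > 0:
            assert est.p_one_tailed_ == pytest.approx(est.p_ / 2, rel=1e-9)
        else:
            assert est.p_one_tailed_ == pytest.approx(1 - est.p_ / 2, rel=1e-9)


class TestTermCollection:
    def test_evidence_filter_and_sources(self):
        frame = pd.DataFrame(
            [
                ("GO:1", "GO", "n", "g1", "EXP"),
                ("GO:1", "GO", "n", "g2", "IEA"),
                ("MP:1", "MP", "n", "g3", "NAS"),
            ],
            columns=["term_id", "source", "name", "gene_id", "evidence"],
        )
        tc = TermCollection(frame).filter_evidence()
        assert tc.to_dict() == {"GO:1": {"g1"}}
        assert TermCollection(frame).sources() == ("GO", "MP")
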