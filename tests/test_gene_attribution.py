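"""Gene DE, attribution rules, Fisher enrichment and allelic ratios."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from retrosilence import gene_attribution as ga
from retrosilence.align import AlignmentRecord


def _rec(start, end, strand="+", k=1, rid=None, seq=None):
    return AlignmentRecord(
        read_id=rid or f"r{start}{strand}",
        target="chr1",
        start=start,
        end=end,
        strand=strand,
        score=end - start,
        nm=0,
        k=k,
        seq=seq or "A" * (end - start),
    )


GENES = pd.DataFrame(
    {
        "gene_id": ["g1", "g2"],
        "chrom": ["chr1", "chr1"],
        "start": [1000, 8000],
        "end": [3000, 10000],
        "strand": ["+", "-"],
    }
)
EXONS = pd.DataFrame(
    {
        "gene_id": ["g1", "g1", "g2"],
        "start": [1000, 2500, 8000],
        "end": [1400, 3000, 10000],
    }
)


class TestExonicCounts:
    def test_strand_matched_counting(self):
        recs = [
            _rec(1100, 1150, "+", rid="a"),   # sense for g1
            _rec(1100, 1150, "-", rid="b"),   # antisense for g1: skipped
            _rec(8100, 8150, "-", rid="c"),   # sense for g2
        ]
        counts, total = ga.exonic_counts(recs, GENES, EXONS)
        assert counts["g1"] == 1.0 and counts["g2"] == 1.0
        assert total == 3.0

    def test_intronic_read_not_counted(self):
        counts, _ = ga.exonic_counts([_rec(1600, 1650, "+")], GENES, EXONS)
        assert counts.sum() == 0.0

    def test_repeat_overlap_excluded(self):
        copies = pd.DataFrame({"copy_id": ["c1"], "start": [1050], "end": [1200]})
        counts, _ = ga.exonic_counts([_rec(1100, 1150, "+")], GENES, EXONS, copies=copies)
        assert counts.sum() == 0.0

    def test_gene_without_exons_rejected(self):
        genes = pd.concat(
            [GENES, pd.DataFrame([{"gene_id": "g3", "chrom": "chr1", "start": 1, "end": 2, "strand": "+"}])]
        )
        with pytest.raises(ValueError, match="zero exonic"):
            ga.exonic_counts([], genes, EXONS)


class TestGeneDe:
    def _run(self, vals, **kw):
        counts = {s: pd.Series(v, index=["g1", "g2"]) for s, v in vals.items()}
        lengths = pd.Series({"g1": 900, "g2": 2000})
        totals = {s: 1e6 for s in vals}
        design = {"k1": "KO", "k2": "KO", "w1": "WT", "w2": "WT"}
        return ga.gene_de(counts, lengths, totals, design, "KO", "WT", **kw)

    def test_null_case_all_unchanged(self):
        out = self._run({s: [100.0, 50.0] for s in ("k1", "k2", "w1", "w2")})
        assert (out["class"] == "unchanged").all()

    def test_bh_oracle(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        m = len(p)
        # oracle: q_i = min over j >= i of m * p_(j) / j
        order = np.argsort(p)
        q_oracle = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            q_oracle[i] = running
        from statsmodels.stats.multitest import multipletests

        _rej, q, _a, _b = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_oracle)
        assert np.allclose(q, 0.04)

    def test_requires_two_replicates(self):
        counts = {s: pd.Series([1.0, 1.0], index=["g1", "g2"]) for s in ("k1", "w1")}
        with pytest.raises(ValueError, match="replicates"):
            ga.gene_de(counts, pd.Series({"g1": 1000, "g2": 1000}),
                       {"k1": 1e6, "w1": 1e6}, {"k1": "KO", "w1": "WT"}, "KO", "WT")


class TestCopyActivation:
    COPIES = pd.DataFrame(
        {
            "copy_id": ["c1", "c2"],
            "family": ["L1", "B1"],
            "chrom": ["chr1", "chr1"],
            "start": [0, 5000],
            "end": [1000, 6000],
            "strand": ["+", "+"],
        }
    )

    def _counts(self, body, flank=0.0):
        df = self.COPIES.copy()
        df["count"] = body
        df["flank_count"] = flank
        return df

    def test_zero_wt_high_ko_activated_if_family_up(self):
        cbs = {
            "k1": self._counts([50.0, 0.0]),
            "k2": self._counts([50.0, 0.0]),
            "w1": self._counts([0.0, 0.0]),
            "w2": self._counts([0.0, 0.0]),
        }
        totals = {s: 1e6 for s in cbs}
        design = {"k1": "KO", "k2": "KO", "w1": "WT", "w2": "WT"}
        out = ga.copy_activation(cbs, totals, design, "KO", "WT", family_up={"L1"})
        row = out.set_index("copy_id").loc["c1"]
        # stabilized rule with WT RPKM-like 0: FC = KO + 1
        assert row["fc"] == pytest.approx(51.0)
        assert bool(row["activated"])

    def test_local_fc_without_family_flag_not_activated(self):
        cbs = {
            "k1": self._counts([0.0, 30.0]),
            "k2": self._counts([0.0, 30.0]),
            "w1": self._counts([0.0, 10.0]),
            "w2": self._counts([0.0, 10.0]),
        }
        totals = {s: 1e6 for s in cbs}
        design = {"k1": "KO", "k2": "KO", "w1": "WT", "w2": "WT"}
        out = ga.copy_activation(cbs, totals, design, "KO", "WT", family_up={"L1"})
        assert not out.set_index("copy_id").loc["c2", "activated"]

    def test_min_count_gate(self):
        cbs = {
            "k1": self._counts([2.0, 0.0]),
            "k2": self._counts([2.0, 0.0]),
            "w1": self._counts([0.0, 0.0]),
            "w2": self._counts([0.0, 0.0]),
        }
        totals = {s: 1e6 for s in cbs}
        design = {"k1": "KO", "k2": "KO", "w1": "WT", "w2": "WT"}
        out = ga.copy_activation(cbs, totals, design, "KO", "WT", family_up={"L1"})
        assert not out["activated"].any()


def _activated(rows):
    return pd.DataFrame(
        rows,
        columns=["copy_id", "family", "start", "end", "strand", "fc",
                 "readthrough_evidence", "activated"],
    )


class TestAttribution:
    GENES = pd.DataFrame(
        {
            "gene_id": ["g1", "g2"],
            "chrom": ["chr1", "chr1"],
            "start": [1_000_000, 3_000_000],
            "end": [1_010_000, 3_010_000],
            "strand": ["+", "+"],
        }
    )

    def _up(self, ids, fc=5.0):
        return pd.DataFrame({"fold_change": fc}, index=pd.Index(ids, name="gene_id"))

    def test_window_boundary_inclusive_at_100kb(self):
        act = _activated([
            ["cA", "L1", 1_010_000 + 100_000 - 500, 1_010_000 + 100_000 + 500, "+", 4.0, False, True],
        ])
        # distance from gene end (1,010,000) to copy start = 99,500: attributed
        recs, summary = ga.attribute_genes(self._up(["g1"]), act, self.GENES)
        assert summary["attributed"] == 1
        act2 = _activated([
            ["cA", "L1", 1_110_001, 1_111_000, "+", 4.0, False, True],
        ])
        recs2, summary2 = ga.attribute_genes(self._up(["g1"]), act2, self.GENES)
        assert summary2["attributed"] == 0  # 100,001 bp away: beyond the window
        act3 = _activated([
            ["cA", "L1", 1_110_000, 1_111_000, "+", 4.0, False, True],
        ])
        _r, summary3 = ga.attribute_genes(self._up(["g1"]), act3, self.GENES)
        assert summary3["attributed"] == 1  # exactly 100,000: inclusive

    def test_intronic_antisense_relation(self):
        act = _activated([
            ["cA", "L1", 1_002_000, 1_008_000, "-", 4.0, True, True],
        ])
        recs, _ = ga.attribute_genes(self._up(["g1"]), act, self.GENES)
        assert recs.loc[0, "relation"] == "intronic-antisense"
        assert recs.loc[0, "distance"] == 0

    def test_nearest_copy_recorded(self):
        act = _activated([
            ["far", "L1", 1_010_000 + 50_000, 1_010_000 + 51_000, "+", 4.0, False, True],
            ["near", "L1", 1_010_000 + 10_000, 1_010_000 + 11_000, "+", 4.0, False, True],
        ])
        recs, _ = ga.attribute_genes(self._up(["g1"]), act, self.GENES)
        assert recs.loc[0, "copy_id"] == "near"

    def test_percentage_order_invariant(self):
        act = _activated([
            ["cA", "L1", 1_015_000, 1_016_000, "+", 4.0, False, True],
        ])
        up1 = self._up(["g1", "g2"])
        up2 = self._up(["g2", "g1"])
        _r1, s1 = ga.attribute_genes(up1, act, self.GENES)
        _r2, s2 = ga.attribute_genes(up2, act, self.GENES)
        assert s1["percentage"] == s2["percentage"]
        assert sum(s1["per_family"].values()) == s1["attributed"]

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            ga.attribute_genes(self._up(["g1"]), _activated([]), self.GENES, window=-1)


class TestAttributionSummaryArithmetic:
    def test_printed_counts_pld6(self):
        s = ga.attribution_summary({"L1": 11, "RLTR10": 2}, total=19)
        assert s["attributed"] == 13
        assert s["percentage"] == 68

    def test_printed_counts_dnmt3l(self):
        s = ga.attribution_summary({"L1": 23, "IAP": 7, "MERVK10/RLTR10": 6, "MMERGLN": 1}, total=91)
        assert s["attributed"] == 37
        assert s["percentage"] == 41

    def test_attributed_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            ga.attribution_summary({"L1": 5}, total=3)


def fisher_oracle(a, b, c, d, alternative="greater"):
    """Hypergeometric enumeration over all tables with the observed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {
        x: comb(c1, x) * comb(n - c1, r1 - x) / comb(n, r1) for x in range(lo, hi + 1)
    }
    if alternative == "greater":
        return sum(p for x, p in probs.items() if x >= a)
    if alternative == "less":
        return sum(p for x, p in probs.items() if x <= a)
    cutoff = probs[a] * (1 + 1e-9)
    return sum(p for p in probs.values() if p <= cutoff)


class TestFisher:
    def test_worked_example(self):
        # [[3,1],[1,3]]: one-sided P = (C(4,3)C(4,1) + C(4,4)C(4,0)) / C(8,4) = 17/70
        p = ga.attribution_enrichment(3, 4, 4, 8)
        assert p == pytest.approx(17 / 70)
        assert fisher_oracle(3, 1, 1, 3) == pytest.approx(17 / 70)

    def test_degenerate_zero_table(self):
        assert ga.attribution_enrichment(0, 5, 0, 10) == pytest.approx(1.0)

    def test_agrees_with_enumeration_small_margins(self):
        from scipy.stats import fisher_exact

        for r1 in range(0, 7):
            for r2 in range(0, 7):
                for c1 in range(0, r1 + r2 + 1):
                    lo, hi = max(0, c1 - r2), min(r1, c1)
                    for a in range(lo, hi + 1):
                        b, c = r1 - a, c1 - a
                        d = r2 - c
                        p_impl = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
                        assert p_impl == pytest.approx(
                            fisher_oracle(a, b, c, d), abs=1e-10
                        ), (a, b, c, d)

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            ga.attribution_enrichment(5, 3, 10, 20)
        with pytest.raises(ValueError):
            ga.attribution_enrichment(2, 5, 1, 20)


class TestNeighborControl:
    def test_single_pair_reports_values_without_test(self):
        attribution = pd.DataFrame({"gene_id": ["g1"]})
        genes = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "chrom": ["chr1"] * 2,
                "start": [0, 50_000],
                "end": [10_000, 60_000],
                "strand": ["+", "+"],
            }
        )
        de = pd.DataFrame({"fold_change": [5.0, 1.0]}, index=pd.Index(["g1", "g2"], name="gene_id"))
        out = ga.neighbor_control(attribution, de, genes)
        assert out["p_value"] is None
        assert out["driven"]["median"] == 5.0
        assert out["n_neighbors"] == 1

    def test_no_driven_genes(self):
        out = ga.neighbor_control(pd.DataFrame(columns=["gene_id"]), pd.DataFrame(), pd.DataFrame())
        assert out["n_driven"] == 0 and out["p_value"] is None


class TestAntisensePirnaGrouping:
    def test_zero_rpm_in_lowest_bin(self):
        de = pd.DataFrame(
            {"fold_change": [1.0, 2.0, 1.5]},
            index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        )
        rpm = pd.Series({"g1": 0.0, "g2": 50.0, "g3": 500.0})
        grouped, _tests = ga.antisense_pirna_grouping(de, rpm, bin_edges=(1.0, 100.0))
        assert str(grouped.loc["g1", "bin"]) == "<=1"
        assert str(grouped.loc["g2", "bin"]) == "1-100"
        assert str(grouped.loc["g3", "bin"]) == ">100"


class TestAllelicRatio:
    SNPS = pd.DataFrame({"chrom": ["chr1"], "pos": [1100], "ref": ["A"], "alt": ["T"]})

    def _reads(self, n_a, n_b):
        recs = []
        for i in range(n_a):
            recs.append(_rec(1080, 1130, "+", rid=f"a{i}", seq="A" * 50))
        for i in range(n_b):
            seq = "A" * 20 + "T" + "A" * 29  # alt base at pos 1100
            recs.append(_rec(1080, 1130, "+", rid=f"b{i}", seq=seq))
        return recs

    def test_ratio_formula(self):
        out = ga.allelic_ratio(self._reads(47, 53), self.SNPS, GENES, EXONS)
        row = out.set_index("gene_id").loc["g1"]
        assert row["ratio"] == pytest.approx(0.47)

    def test_mismatching_base_discarded(self):
        recs = [_rec(1080, 1130, "+", rid="x", seq="A" * 20 + "G" + "A" * 29)]
        out = ga.allelic_ratio(recs, self.SNPS, GENES, EXONS)
        assert out.attrs["discarded"]["mismatch"] == 1
        assert np.isnan(out.set_index("gene_id").loc["g1", "ratio"])

    def test_conflicting_snps_discarded(self):
        snps = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "pos": [1100, 1110], "ref": ["A", "A"], "alt": ["T", "T"]}
        )
        seq = "A" * 20 + "T" + "A" * 9 + "A" + "A" * 19  # allele B at 1100, A at 1110
        recs = [_rec(1080, 1130, "+", rid="x", seq=seq)]
        out = ga.allelic_ratio(recs, snps, GENES, EXONS)
        assert out.attrs["discarded"]["conflict"] == 1
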