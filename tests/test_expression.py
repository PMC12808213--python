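"""CPM, expression filters, DE classification, arm comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spliceaudit import synthdata
from spliceaudit.expression import (
    DESummary,
    bh_adjust,
    classify_de,
    classify_unique,
    compare_arms,
    cpm,
    diff_summary,
    filter_transcripts,
    intersect_loci,
    top_by_foldchange,
)

CTRL = ["c1", "c2"]
AD = ["a1", "a2"]


def table(rows):
    """rows: (transcript_id, c1, c2, a1, a2)."""
    return pd.DataFrame(rows, columns=["transcript_id"] + CTRL + AD)


def brute_force_bh(p):
    """Independent BH step-up: sort, scale by m/rank, cumulative min from
    the largest rank down, cap at 1, restore order."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        rank = m - rank_from_top
        running = min(running, min(1.0, p[idx] * m / rank))
        adjusted[idx] = running
    return adjusted


class TestCPM:
    def test_unit_count_in_million_library(self):
        counts = pd.DataFrame({"s1": [1, 10**6 - 1]})
        assert cpm(counts).iloc[0, 0] == pytest.approx(1.0)

    def test_all_zero_transcript_stays_zero(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [0, 3]})
        assert (cpm(counts).iloc[0] == 0).all()

    def test_column_sums_are_one_million(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 500, size=(50, 4)))
        assert cpm(counts).sum(axis=0).values == pytest.approx([1e6] * 4)

    def test_zero_library_size_names_sample(self):
        counts = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            cpm(counts)


class TestClassifyUnique:
    @pytest.mark.parametrize(
        "ctrl,ad,expected",
        [
            ([0, 0], [3, 0], "ad_only"),
            ([0, 5], [2, 0], "both"),
            ([1, 0], [0, 0], "control_only"),
            ([0, 0], [0, 0], "neither"),
        ],
    )
    def test_classes(self, ctrl, ad, expected):
        t = table([("t1", *ctrl, *ad)])
        assert classify_unique(t, CTRL, AD).iloc[0] == expected

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            classify_unique(table([("t1", 1, 1, 1, 1)]), [], AD)


class TestFilterTranscripts:
    def test_reasons_and_retention_arithmetic(self):
        """100 transcripts: 10 unique, 5 all-zero low-expression -> 85."""
        rows = []
        for i in range(85):
            rows.append((f"keep{i}", 5, 5, 5, 5))
        for i in range(5):
            rows.append((f"adonly{i}", 0, 0, 9, 0))
        for i in range(5):
            rows.append((f"ctrlonly{i}", 9, 0, 0, 0))
        for i in range(5):
            rows.append((f"low{i}", 0, 0, 0, 0))
        retained, log = filter_transcripts(table(rows), CTRL, AD)
        assert len(retained) == 85
        reasons = log.set_index("transcript_id")["reason"]
        assert (reasons.loc[[f"adonly{i}" for i in range(5)]] == "unique").all()
        assert (reasons.loc[[f"low{i}" for i in range(5)]] == "low_expression").all()

    def test_no_retained_transcript_is_unique(self, expression_tables):
        counts = expression_tables["counts_armA"]
        ctrl = expression_tables["control_samples"]
        ad = expression_tables["ad_samples"]
        retained, _ = filter_transcripts(counts, ctrl, ad)
        classes = classify_unique(retained, ctrl, ad)
        assert not classes.isin(["ad_only", "control_only"]).any()


class TestBHAdjust:
    def test_single_p_is_unchanged(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_worked_step_up(self):
        # 0.01*3/1, 0.02*3/2, 0.03*3/3 then cumulative min from the top
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        assert bh_adjust([1.0] * 5) == pytest.approx([1.0] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.random(size=int(rng.integers(1, 51)))
            assert bh_adjust(p) == pytest.approx(brute_force_bh(p), abs=1e-12)


class TestClassifyDE:
    def de_table(self, rows):
        return pd.DataFrame(rows, columns=["transcript_id", "log2FC", "pvalue"])

    def test_relaxed_uses_raw_p(self):
        out, summary = classify_de(
            self.de_table([("t1", 2.0, 0.005), ("t2", -1.0, 0.02)]), "relaxed"
        )
        assert list(out["status"]) == ["up", "ns"]
        assert (summary.down, summary.ns, summary.up) == (0, 1, 1)

    def test_stringent_uses_adjusted_p(self):
        t = self.de_table([("t1", 2.0, 0.2), ("t2", 1.0, 0.9)])
        out, summary = classify_de(t, "stringent")
        assert (out["status"] == "ns").all()
        assert summary.total == 0

    def test_precomputed_padj_respected(self):
        t = self.de_table([("t1", -2.0, 0.04)])
        t["padj"] = [0.04]
        _, summary = classify_de(t, "stringent")
        assert summary.down == 1

    def test_zero_log2fc_significant_stays_ns(self):
        _, summary = classify_de(self.de_table([("t1", 0.0, 1e-9)]), "relaxed")
        assert summary.total == 0 and summary.ns == 1

    def test_missing_columns_schema_error(self):
        with pytest.raises(KeyError, match="log2FC"):
            classify_de(pd.DataFrame({"transcript_id": [], "pvalue": []}))

    def test_planted_summary_recovered(self, expression_tables):
        truth = expression_tables["truth"]
        de = expression_tables["de_armA"]
        in_arm = truth[truth["arm"] != "armB_only"]
        _, summary = classify_de(de, "relaxed")
        assert summary.up == (in_arm["status"] == "de_up").sum()
        assert summary.down == (in_arm["status"] == "de_down").sum()


class TestCompareArms:
    def coords(self, keys):
        return pd.DataFrame(
            [(f"t{i}", k[0], k[1], k[2], k[3]) for i, k in enumerate(keys)],
            columns=["transcript_id", "chrom", "start", "end", "strand"],
        )

    def test_partition_of_overlapping_sets(self):
        k1, k2, k3 = ("c", 1, 2, "+"), ("c", 3, 4, "+"), ("c", 5, 6, "-")
        comp = compare_arms(self.coords([k1, k2]), self.coords([k2, k3]))
        assert (len(comp.shared), len(comp.a_only), len(comp.b_only)) == (1, 1, 1)

    def test_identical_arms_have_no_exclusives(self):
        keys = [("c", i, i + 1, "+") for i in range(5)]
        comp = compare_arms(self.coords(keys), self.coords(keys))
        assert not comp.a_only and not comp.b_only

    def test_duplicate_keys_within_arm_rejected(self):
        k = ("c", 1, 2, "+")
        with pytest.raises(ValueError, match="duplicate"):
            compare_arms(self.coords([k, k]), self.coords([k]))

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.sets(st.integers(0, 40), max_size=30),
        b=st.sets(st.integers(0, 40), max_size=30),
    )
    def test_cardinality_identities(self, a, b):
        comp = compare_arms(a, b)
        assert len(comp.shared) + len(comp.a_only) == len(a)
        assert len(comp.shared) + len(comp.b_only) == len(b)
        assert comp.shared.isdisjoint(comp.a_only)
        assert comp.shared.isdisjoint(comp.b_only)

    def test_planted_exclusive_counts_recovered(self, expression_tables):
        truth = expression_tables["truth"]
        comp = compare_arms(
            expression_tables["counts_armA"], expression_tables["counts_armB"]
        )
        assert len(comp.a_only) == (truth["arm"] == "armA_only").sum()
        assert len(comp.b_only) == (truth["arm"] == "armB_only").sum()
        assert len(comp.shared) == (truth["arm"] == "both_arms").sum()


class TestSummaryArithmetic:
    def test_arm_totals_and_delta(self):
        unfiltered = DESummary("relaxed", down=53, ns=60_397, up=363)
        filtered = DESummary("relaxed", down=35, ns=60_163, up=466)
        delta = diff_summary(unfiltered, filtered)
        assert unfiltered.total == 416
        assert filtered.total == 501
        assert delta["delta_total"] == 85
        assert delta["delta_down"] == -18
        assert delta["delta_up"] == 103

    def test_identical_summaries_zero_delta(self):
        s = DESummary("relaxed", 5, 10, 7)
        assert diff_summary(s, s)["delta_total"] == 0

    def test_empty_second_arm(self):
        a = DESummary("relaxed", 5, 0, 7)
        assert diff_summary(a, DESummary("relaxed", 0, 0, 0))["delta_total"] == -12

    def test_regime_mismatch_rejected(self):
        with pytest.raises(ValueError, match="regime"):
            diff_summary(DESummary("relaxed", 1, 1, 1), DESummary("stringent", 1, 1, 1))


class TestLoci:
    def test_intersection_sorted(self):
        shared = intersect_loci(
            ["HEATR5A", "MBNL3", "X"], ["MBNL3", "Y", "HEATR5A"]
        )
        assert shared == ["HEATR5A", "MBNL3"]

    def test_disjoint_sets_empty(self):
        assert intersect_loci(["A"], ["B"]) == []

    def test_planted_common_loci_recovered(self):
        common = [f"L{i}" for i in range(6)]
        de_genes = common + ["only_de1", "only_de2"]
        splice_genes = common + ["only_splice"]
        assert intersect_loci(de_genes, splice_genes) == sorted(common)


class TestTopByFoldchange:
    def de(self, rows):
        df = pd.DataFrame(
            rows, columns=["transcript_id", "log2FC", "pvalue", "status"]
        )
        return df

    def test_magnitude_ranking(self):
        t = self.de([("a", 3.0, 0.001, "up"), ("b", -4.0, 0.001, "down"),
                     ("c", 1.0, 0.001, "up"), ("d", 9.0, 0.5, "ns")])
        top = top_by_foldchange(t, 2)
        assert list(top["transcript_id"]) == ["b", "a"]

    def test_n_larger_than_set_returns_all_significant(self):
        t = self.de([("a", 1.0, 0.01, "up"), ("b", -2.0, 0.01, "down")])
        assert len(top_by_foldchange(t, 10)) == 2

    def test_tie_breaks_by_raw_p_then_id(self):
        t = self.de([("b", 2.0, 0.002, "up"), ("a", -2.0, 0.001, "down"),
                     ("c", 2.0, 0.001, "up")])
        top = top_by_foldchange(t, 3)
        assert list(top["transcript_id"]) == ["a", "c", "b"]

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            top_by_foldchange(self.de([]), 0)
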