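"""Comparative transcript-expression analysis between processing arms.

Implements the downstream expression framework used to compare an
unfiltered against a confidence-filtered alignment arm: CPM
normalization, exclusion of uniquely expressed transcripts (nonzero in
one condition group and all-zero in the other) and of low-expression
transcripts (total CPM across all samples below 0.1), BH-controlled
differential-expression calls under a stringent (adjusted p < 0.05) or
relaxed (raw p < 0.01) regime with no fold-change cut-off, a
coordinate-keyed shared/exclusive partition of transcript sets between
arms, locus intersection with splicing-event results, and
fold-change-magnitude ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cpm",
    "classify_unique",
    "filter_transcripts",
    "bh_adjust",
    "DESummary",
    "classify_de",
    "ArmComparison",
    "compare_arms",
    "diff_summary",
    "intersect_loci",
    "top_by_foldchange",
    "MIN_TOTAL_CPM",
    "STRINGENT_ALPHA",
    "RELAXED_ALPHA",
]

logger = logging.getLogger(__name__)

MIN_TOTAL_CPM = 0.1
STRINGENT_ALPHA = 0.05
RELAXED_ALPHA = 0.01

COORD_COLS = ["chrom", "start", "end", "strand"]


def _count_matrix(table: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
    return table[list(samples)]


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: counts / column library size * 1e6.

    ``counts`` holds one column per sample.  A zero library size is an
    error naming the offending sample.
    """
    libsize = counts.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return counts / libsize * 1e6


def classify_unique(
    table: pd.DataFrame,
    control: Sequence[str],
    ad: Sequence[str],
    min_expr_count: int = 1,
) -> pd.Series:
    """Unique-expression class per transcript.

    A transcript is expressed in a group iff its raw count reaches
    ``min_expr_count`` (default 1, i.e. any positive count) in at least
    one of that group's samples; ``ad_only`` transcripts are expressed
    in AD and nowhere in control, symmetrically for ``control_only``;
    both/neither otherwise.
    """
    if not len(control) or not len(ad):
        raise ValueError("both groups need at least one sample")
    in_ctrl = (table[list(control)] >= min_expr_count).any(axis=1)
    in_ad = (table[list(ad)] >= min_expr_count).any(axis=1)
    out = pd.Series("neither", index=table.index, dtype=object)
    out[in_ctrl & in_ad] = "both"
    out[in_ad & ~in_ctrl] = "ad_only"
    out[in_ctrl & ~in_ad] = "control_only"
    return out


def filter_transcripts(
    table: pd.DataFrame,
    control: Sequence[str],
    ad: Sequence[str],
    min_total_cpm: float = MIN_TOTAL_CPM,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression filters applied before DE classification.

    Drops uniquely expressed transcripts (either direction), then
    transcripts whose CPM summed over *all* samples is below
    ``min_total_cpm``.  Returns (retained, exclusion log) where the log
    records one (transcript_id, reason) row per excluded transcript.
    """
    samples = list(control) + list(ad)
    unique_class = classify_unique(table, control, ad)
    is_unique = unique_class.isin(["ad_only", "control_only"])

    total_cpm = cpm(_count_matrix(table, samples)).sum(axis=1)
    low = (total_cpm < min_total_cpm) & ~is_unique

    reasons = []
    for tid, uniq, lo in zip(table["transcript_id"], is_unique, low):
        if uniq:
            reasons.append((tid, "unique"))
        elif lo:
            reasons.append((tid, "low_expression"))
    retained = table[~(is_unique | low)].reset_index(drop=True)
    log = pd.DataFrame(reasons, columns=["transcript_id", "reason"])
    return retained, log


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DESummary:
    """Down/ns/up counts under one significance regime."""

    regime: str
    down: int
    ns: int
    up: int

    @property
    def total(self) -> int:
        return self.down + self.up

    def to_series(self) -> pd.Series:
        return pd.Series(
            {"down": self.down, "ns": self.ns, "up": self.up}, name=self.regime
        )


def classify_de(
    de_table: pd.DataFrame, regime: str = "stringent"
) -> tuple[pd.DataFrame, DESummary]:
    """Differential-expression status per transcript.

    ``stringent``: significant iff BH-adjusted p < 0.05; ``relaxed``:
    significant iff raw p < 0.01.  No fold-change cut-off in either
    regime; direction comes from the sign of log2FC.  A significant
    transcript with exactly zero log2FC is left ``ns`` with a warning.
    Returns the table with ``padj``/``status`` columns and the summary.
    """
    required = {"transcript_id", "log2FC", "pvalue"}
    if missing := required - set(de_table.columns):
        raise KeyError(f"DE table missing columns: {sorted(missing)}")
    if regime not in ("stringent", "relaxed"):
        raise ValueError(f"unknown regime {regime!r}")

    out = de_table.copy()
    if "padj" not in out.columns:
        out["padj"] = bh_adjust(out["pvalue"])
    if regime == "stringent":
        significant = out["padj"] < STRINGENT_ALPHA
    else:
        significant = out["pvalue"] < RELAXED_ALPHA

    zero_fc = significant & (out["log2FC"] == 0)
    if zero_fc.any():
        logger.warning(
            "%d significant transcripts with zero log2FC left 'ns'", zero_fc.sum()
        )
    status = pd.Series("ns", index=out.index, dtype=object)
    status[significant & (out["log2FC"] > 0)] = "up"
    status[significant & (out["log2FC"] < 0)] = "down"
    out["status"] = status
    summary = DESummary(
        regime,
        int((status == "down").sum()),
        int((status == "ns").sum()),
        int((status == "up").sum()),
    )
    return out, summary


@dataclass
class ArmComparison:
    """Shared/exclusive partition of transcript sets between two arms."""

    arm_a: str
    arm_b: str
    shared: set
    a_only: set
    b_only: set
    mode: str = "exact_coords"

    @property
    def counts(self) -> dict[str, int]:
        return {
            self.arm_a: len(self.shared) + len(self.a_only),
            self.arm_b: len(self.shared) + len(self.b_only),
            "shared": len(self.shared),
            f"{self.arm_a}_exclusive": len(self.a_only),
            f"{self.arm_b}_exclusive": len(self.b_only),
        }

    def to_venn(self) -> dict:
        return {"mode": self.mode, **self.counts}


def _arm_keys(arm: pd.DataFrame | Iterable, mode: str, label: str) -> set:
    if not isinstance(arm, pd.DataFrame):
        return set(arm)
    if mode == "exact_coords":
        keys = list(zip(*(arm[c] for c in COORD_COLS)))
    elif mode == "transcript_id":
        keys = list(arm["transcript_id"])
    else:
        raise ValueError(f"unknown matching mode {mode!r}")
    dupes = pd.Series(keys).value_counts()
    dupes = dupes[dupes > 1]
    if len(dupes):
        raise ValueError(
            f"duplicate keys within arm {label!r}: {list(dupes.index[:5])}"
        )
    return set(keys)


def compare_arms(
    arm_a: pd.DataFrame | Iterable,
    arm_b: pd.DataFrame | Iterable,
    mode: str = "exact_coords",
    labels: tuple[str, str] = ("armA", "armB"),
) -> ArmComparison:
    """Partition two transcript sets into shared and arm-exclusive keys.

    The default key is the exact genomic coordinate tuple
    (chrom, start, end, strand), mirroring coordinate-based matching of
    assemblies from two processing arms; ``transcript_id`` mode matches
    on identifiers instead.
    """
    a = _arm_keys(arm_a, mode, labels[0])
    b = _arm_keys(arm_b, mode, labels[1])
    return ArmComparison(
        labels[0], labels[1], shared=a & b, a_only=a - b, b_only=b - a, mode=mode
    )


def diff_summary(summary_a: DESummary, summary_b: DESummary) -> dict:
    """Per-direction and total DE-count deltas between two arms."""
    if summary_a.regime != summary_b.regime:
        raise ValueError(
            f"regime mismatch: {summary_a.regime!r} vs {summary_b.regime!r}"
        )
    return {
        "regime": summary_a.regime,
        "total_a": summary_a.total,
        "total_b": summary_b.total,
        "delta_total": summary_b.total - summary_a.total,
        "delta_down": summary_b.down - summary_a.down,
        "delta_up": summary_b.up - summary_a.up,
    }


def intersect_loci(
    de_transcript_genes: Iterable[str], splice_event_genes: Iterable[str]
) -> list[str]:
    """Sorted intersection of two (deduplicated) gene-locus lists."""
    return sorted(set(de_transcript_genes) & set(splice_event_genes))


def top_by_foldchange(de_table: pd.DataFrame, n: int) -> pd.DataFrame:
    """Top-n significant transcripts by |log2FC|.

    Ties break by ascending raw p-value, then transcript ID.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if "status" not in de_table.columns:
        raise KeyError("DE table must carry a 'status' column (run classify_de)")
    sig = de_table[de_table["status"].isin(["up", "down"])].copy()
    sig["_mag"] = sig["log2FC"].abs()
    sig = sig.sort_values(
        ["_mag", "pvalue", "transcript_id"], ascending=[False, True, True]
    ).drop(columns="_mag")
    return sig.head(n).reset_index(drop=True)
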