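"""Junction-level quality metrics and before/after filtering comparison.

Five metric families summarise the plausibility of a junction set:
read-support distribution (median, percent with support >= 5), canonical
GT-AG motif share, intron-length distribution (median, percent strictly
over 100 kb), and per-gene junction burden (mean distinct junctions and
mean junction reads per annotated gene, zero-junction genes included).
Filtering out spurious junctions should raise the support and canonical
shares and lower the ultralong-intron share.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_EVEN
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .junctions import GeneSpan, SpliceJunction, junctions_per_gene

__all__ = ["JunctionQCReport", "compute_qc", "compare_qc", "write_report"]

logger = logging.getLogger(__name__)

ULTRALONG_BP = 100_000
WELL_SUPPORTED = 5


@dataclass
class JunctionQCReport:
    """Five-metric junction QC summary.

    All percents are over distinct junctions; medians are standard
    (mean of the middle two for even n).  An empty junction set yields
    ``None`` in every field rather than zeros.
    """

    n_distinct_junctions: int
    median_read_support: float | None
    pct_support_ge5: float | None
    pct_canonical: float | None
    median_intron_length: float | None
    pct_intron_gt_100kb: float | None
    mean_junctions_per_gene_distinct: float | None = None
    mean_junctions_per_gene_reads: float | None = None
    annotation: str | None = None

    def to_dict(self, rounded: bool = False) -> dict:
        d = asdict(self)
        if rounded:
            for key, value in d.items():
                if isinstance(value, float):
                    d[key] = _round2(value)
        return d


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def compute_qc(
    junctions: Sequence[SpliceJunction],
    gene_spans: Sequence[GeneSpan] | None = None,
    annotation: str | None = None,
    nonzero_genes_only: bool = False,
) -> JunctionQCReport:
    """Compute the junction QC report.

    Per-gene means are filled only when ``gene_spans`` is given; they
    average over *every* annotated gene, including genes with zero
    junctions, unless ``nonzero_genes_only`` restricts the mean to genes
    carrying at least one junction.
    """
    n = len(junctions)
    if n == 0:
        logger.warning("empty junction set: QC metrics undefined")
        return JunctionQCReport(0, None, None, None, None, None, None, None, annotation)

    support = np.array([j.read_support for j in junctions])
    lengths = np.array([j.intron_length for j in junctions])
    canonical = sum(1 for j in junctions if j.motif_class == "GT-AG")

    report = JunctionQCReport(
        n_distinct_junctions=n,
        median_read_support=float(np.median(support)),
        pct_support_ge5=100.0 * int((support >= WELL_SUPPORTED).sum()) / n,
        pct_canonical=100.0 * canonical / n,
        median_intron_length=float(np.median(lengths)),
        pct_intron_gt_100kb=100.0 * int((lengths > ULTRALONG_BP).sum()) / n,
        annotation=annotation,
    )
    if gene_spans is not None:
        per_gene = junctions_per_gene(junctions, gene_spans)
        if nonzero_genes_only:
            per_gene = per_gene[per_gene["distinct"] > 0]
        if len(per_gene):
            report.mean_junctions_per_gene_distinct = float(per_gene["distinct"].mean())
            report.mean_junctions_per_gene_reads = float(per_gene["reads"].mean())
    return report


_METRICS = [
    "n_distinct_junctions",
    "median_read_support",
    "pct_support_ge5",
    "pct_canonical",
    "median_intron_length",
    "pct_intron_gt_100kb",
    "mean_junctions_per_gene_distinct",
    "mean_junctions_per_gene_reads",
]


def compare_qc(before: JunctionQCReport, after: JunctionQCReport) -> pd.DataFrame:
    """Per-metric (before, after, delta, direction) table.

    Raises when the two reports carry different annotation identifiers.
    """
    if (
        before.annotation is not None
        and after.annotation is not None
        and before.annotation != after.annotation
    ):
        raise ValueError(
            f"reports computed against different annotations: "
            f"{before.annotation!r} vs {after.annotation!r}"
        )
    rows = []
    bd, ad = before.to_dict(), after.to_dict()
    for metric in _METRICS:
        b, a = bd[metric], ad[metric]
        if b is None or a is None:
            rows.append((metric, b, a, None, "undefined"))
            continue
        delta = a - b
        direction = "increase" if delta > 0 else "decrease" if delta < 0 else "unchanged"
        rows.append((metric, b, a, delta, direction))
    return pd.DataFrame(rows, columns=["metric", "before", "after", "delta", "direction"])


def write_report(
    report: JunctionQCReport | pd.DataFrame, path: str | Path
) -> None:
    """Serialize a QC report (JSON) or comparison table (TSV/JSON by suffix).

    Floats are rounded to 2 decimals (round-half-even) at serialization
    only.
    """
    path = Path(path)
    if isinstance(report, JunctionQCReport):
        path.write_text(json.dumps(report.to_dict(rounded=True), indent=2) + "\n")
        return
    df = report.copy()
    for col in ("before", "after", "delta"):
        df[col] = [
            _round2(v) if isinstance(v, float) else v for v in df[col]
        ]
    if path.suffix == ".json":
        path.write_text(df.to_json(orient="records", indent=2) + "\n")
    else:
        df.to_csv(path, sep="\t", index=False)
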