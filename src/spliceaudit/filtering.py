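"""Confidence scoring of splice junctions and alignment filtering.

A pluggable confidence function assigns each distinct junction a score
in [0, 1]; alignment records carrying any junction below a threshold
(default 0.1, the conventional cleaning cut-off) are removed from the
SAM.  Three scorers are provided:

* ``heuristic`` — a documented, deterministic combination of motif
  class, read support and intron length (this package's own stand-in
  for an external learned scorer);
* ``oracle`` — ground-truth lookup against a generator truth table
  (1.0 for true junctions, 0.0 for spurious), used as a test oracle;
* ``external-table`` — scores loaded from a TSV, so output of a real
  splice-site scoring tool can be plugged in.

Filtering is stream-based on text SAM: header lines and retained
records are copied verbatim, so the output header is byte-identical and
no record is mutated.  Junction-free and unmapped records are always
retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from .junctions import (
    DEFAULT_MIN_ANCHOR,
    SpliceJunction,
    parse_cigar,
    read_junctions,
)

__all__ = [
    "DEFAULT_THRESHOLD",
    "HeuristicWeights",
    "score_heuristic",
    "score_oracle",
    "score_junctions",
    "load_score_table",
    "filter_alignment",
    "FilterSummary",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.1

_MOTIF_SCORE = {"GT-AG": 1.0, "GC-AG": 0.6, "AT-AC": 0.5, "other": 0.0}
_LENGTH_SOFT_CAP = 100_000
_SUPPORT_HALF_SAT = 5  # support at which the coverage term reaches 0.5


@dataclass(frozen=True)
class HeuristicWeights:
    motif: float = 0.6
    coverage: float = 0.2
    length: float = 0.2

    def __post_init__(self) -> None:
        total = self.motif + self.coverage + self.length
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"heuristic weights must sum to 1, got {total}")


def score_heuristic(
    junction: SpliceJunction, weights: HeuristicWeights = HeuristicWeights()
) -> float:
    """Deterministic junction confidence in [0, 1].

    ``w_m * m + w_c * c + w_l * l`` where m scores the motif class
    (GT-AG 1.0, GC-AG 0.6, AT-AC 0.5, other 0.0), c = support /
    (support + 5) saturates with read support, and l = 1 for introns up
    to 100 kb, decaying as exp(-(length - 100000) / 100000) beyond.
    """
    if junction.read_support < 1:
        raise ValueError("junction read_support must be >= 1")
    m = _MOTIF_SCORE.get(junction.motif_class, 0.0)
    c = junction.read_support / (junction.read_support + _SUPPORT_HALF_SAT)
    length = junction.intron_length
    if length <= _LENGTH_SOFT_CAP:
        l = 1.0
    else:
        l = math.exp(-(length - _LENGTH_SOFT_CAP) / _LENGTH_SOFT_CAP)
    score = weights.motif * m + weights.coverage * c + weights.length * l
    return min(1.0, max(0.0, score))


def _truth_label_map(truth: pd.DataFrame) -> dict[tuple[str, int, int], bool]:
    return {
        (row.chrom, int(row.intron_start), int(row.intron_end)): row.label == "true"
        for row in truth.itertuples(index=False)
    }


def score_oracle(
    junction: SpliceJunction, truth: pd.DataFrame | Mapping
) -> float:
    """Ground-truth confidence: 1.0 for true junctions, 0.0 for spurious."""
    labels = truth if isinstance(truth, Mapping) else _truth_label_map(truth)
    key = junction.interval_key
    if key not in labels:
        raise LookupError(f"junction {key} absent from truth table")
    return 1.0 if labels[key] else 0.0


def score_junctions(
    junctions: Sequence[SpliceJunction],
    scorer: str = "heuristic",
    truth: pd.DataFrame | None = None,
    weights: HeuristicWeights = HeuristicWeights(),
) -> dict[tuple[str, int, int], float]:
    """Score every junction; returns (chrom, start, end) -> confidence."""
    if scorer == "heuristic":
        return {j.interval_key: score_heuristic(j, weights) for j in junctions}
    if scorer == "oracle":
        if truth is None:
            raise ValueError("oracle scorer requires a truth table")
        labels = _truth_label_map(truth)
        return {j.interval_key: score_oracle(j, labels) for j in junctions}
    raise ValueError(f"unknown scorer {scorer!r}")


def load_score_table(path: str | Path) -> dict[tuple[str, int, int], float]:
    """Load a junction score TSV (chrom, intron_start, intron_end, strand,
    confidence); validates range and rejects duplicate keys, reporting
    line numbers."""
    scores: dict[tuple[str, int, int], float] = {}
    seen_full: set = set()
    with open(path) as fh:
        header = fh.readline()
        if not header:
            logger.warning("empty score table %s", path)
            return {}
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            chrom, start, end, strand, conf = fields[:5]
            try:
                key_full = (chrom, int(start), int(end), strand)
                confidence = float(conf)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if not 0.0 <= confidence <= 1.0:
                raise ValueError(
                    f"{path}:{lineno}: confidence {confidence} outside [0, 1]"
                )
            if key_full in seen_full:
                raise ValueError(f"{path}:{lineno}: duplicate key {key_full}")
            seen_full.add(key_full)
            key = key_full[:3]
            # Same interval on both strands: keep the lower confidence.
            scores[key] = min(scores[key], confidence) if key in scores else confidence
    return scores


@dataclass
class FilterSummary:
    total_records: int
    junction_bearing: int
    removed: int
    threshold: float

    @property
    def removal_fraction(self) -> float:
        return self.removed / self.junction_bearing if self.junction_bearing else 0.0


_FLAG_UNMAPPED = 0x4


def filter_alignment(
    sam_in: str | Path,
    scores: Mapping[tuple[str, int, int], float] | Callable[[tuple], float],
    sam_out: str | Path,
    threshold: float = DEFAULT_THRESHOLD,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    strict: bool = True,
) -> tuple[FilterSummary, pd.DataFrame]:
    """Remove records carrying low-confidence junctions from a SAM.

    A record is dropped iff any junction it spans has confidence below
    ``threshold``.  Header lines and retained records are copied
    byte-for-byte in input order.  In strict mode a junction without a
    score is an error; in lenient mode it defaults to 1.0 (logged).

    Returns the summary and a per-record decision table over
    junction-bearing records (read_id, removed, triggering keys).
    """
    lookup = scores if callable(scores) else scores.get
    missing: set = set()
    decisions = []
    total = bearing = removed = 0
    with open(sam_in) as src, open(sam_out, "w", newline="") as dst:
        for line in src:
            if line.startswith("@"):
                dst.write(line)
                continue
            total += 1
            fields = line.rstrip("\n").split("\t")
            qname, flag, chrom, pos1, cigar = (
                fields[0], int(fields[1]), fields[2], int(fields[3]), fields[5],
            )
            if flag & _FLAG_UNMAPPED or cigar == "*":
                dst.write(line)
                continue
            ops = parse_cigar(cigar, qname)
            intervals = read_junctions((pos1 - 1, ops), min_anchor=min_anchor)
            if not intervals:
                dst.write(line)
                continue
            bearing += 1
            triggering = []
            for start, end in intervals:
                key = (chrom, start, end)
                conf = lookup(key)
                if conf is None:
                    missing.add(key)
                    conf = 1.0
                if conf < threshold:
                    triggering.append(key)
            drop = bool(triggering)
            if drop:
                removed += 1
            else:
                dst.write(line)
            decisions.append(
                (
                    qname,
                    drop,
                    ";".join(f"{c}:{s}-{e}" for c, s, e in triggering),
                )
            )
    if missing:
        if strict:
            raise LookupError(
                f"{len(missing)} junction keys without scores, e.g. "
                f"{sorted(missing)[:5]}"
            )
        logger.warning(
            "%d junction keys without scores defaulted to confidence 1.0",
            len(missing),
        )
    summary = FilterSummary(total, bearing, removed, threshold)
    table = pd.DataFrame(decisions, columns=["read_id", "removed", "triggering"])
    return summary, table
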