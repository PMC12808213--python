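"""Keyword-based gene literature-relevance survey.

Screens per-gene text documents (an offline corpus standing in for gene
database pages) for a curated list of keyword stems associated with
Alzheimer's disease pathology.  Stems are deliberate truncations
("neurodegenerat" matches neurodegeneration and neurodegenerative), so
matching is case-insensitive substring containment with no word
boundary requirement.  The pipeline is: dedupe the input symbol list,
map symbols to numeric gene IDs, grep each gene's document, and report
the relevant share.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .reporting import percent

__all__ = [
    "DEFAULT_KEYWORDS",
    "KeywordSet",
    "dedupe_genes",
    "map_symbols",
    "match_keywords",
    "survey",
    "relevance_summary",
]

logger = logging.getLogger(__name__)

# Curated stems capturing Alzheimer's-pathology vocabulary.
DEFAULT_KEYWORDS = (
    "Alzheimer",
    "amyloid",
    "astrocyt",
    "cognit",
    "dement",
    "memor",
    "microgli",
    "neurodegenerat",
    "neuroinflamm",
    "neuro",
    "plaque",
    "tangl",
    "tau",
)

_TAG_RE = re.compile(r"<[^>]+>")


@dataclass(frozen=True)
class KeywordSet:
    """An ordered, case-folded-unique list of keyword stems."""

    stems: tuple[str, ...] = DEFAULT_KEYWORDS

    def __post_init__(self) -> None:
        if not self.stems:
            raise ValueError("keyword set must be non-empty")
        folded = [s.casefold() for s in self.stems]
        if any(not s for s in folded):
            raise ValueError("empty keyword stem")
        if len(set(folded)) != len(folded):
            raise ValueError("keyword stems must be unique after case-folding")

    def __iter__(self):
        return iter(self.stems)

    def __len__(self) -> int:
        return len(self.stems)

    @classmethod
    def from_file(cls, path: str | Path) -> "KeywordSet":
        stems = tuple(
            line.strip()
            for line in Path(path).read_text().splitlines()
            if line.strip()
        )
        return cls(stems)


def dedupe_genes(symbols: Iterable[str]) -> list[str]:
    """Sorted, case-insensitively unique gene symbols.

    Dedupe is on the case-folded key, keeping the first-seen casing;
    the result is lexicographically sorted.
    """
    seen: dict[str, str] = {}
    n_in = 0
    for sym in symbols:
        n_in += 1
        seen.setdefault(sym.casefold(), sym)
    out = sorted(seen.values())
    logger.info("deduped %d symbols to %d", n_in, len(out))
    return out


def map_symbols(
    symbols: Sequence[str], mapping_path: str | Path
) -> tuple[list[str], list[str]]:
    """Map gene symbols to gene IDs via a two-column TSV.

    Returns (IDs in input order, unmapped symbols).  Conflicting
    duplicate mapping rows are fatal; malformed rows report their line
    number.
    """
    table: dict[str, str] = {}
    with open(mapping_path) as fh:
        first = fh.readline()
        lines = [(1, first)] if first else []
        lines += [(i, l) for i, l in enumerate(fh, 2)]
    for lineno, line in lines:
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{mapping_path}:{lineno}: expected 2 columns")
        symbol, gene_id = fields[0].strip(), fields[1].strip()
        if lineno == 1 and symbol.casefold() in ("symbol", "gene_symbol"):
            continue
        if not symbol or not gene_id:
            raise ValueError(f"{mapping_path}:{lineno}: empty field")
        key = symbol.casefold()
        if key in table and table[key] != gene_id:
            raise ValueError(
                f"{mapping_path}:{lineno}: conflicting IDs for symbol "
                f"{symbol!r}: {table[key]} vs {gene_id}"
            )
        table[key] = gene_id
    mapped, unmapped = [], []
    for sym in symbols:
        gene_id = table.get(sym.casefold())
        if gene_id is None:
            unmapped.append(sym)
        else:
            mapped.append(gene_id)
    return mapped, unmapped


def strip_html(text: str) -> str:
    """Drop markup tags so corpus files saved as HTML pages still grep
    like plain text."""
    return _TAG_RE.sub(" ", text)


def match_keywords(
    text: str, keywords: KeywordSet | Sequence[str] = DEFAULT_KEYWORDS
) -> list[str]:
    """All keyword stems contained in the text, case-insensitively.

    Overlapping stems are all reported ("neurodegeneration" matches both
    "neurodegenerat" and "neuro").
    """
    low = strip_html(text).casefold()
    return [stem for stem in keywords if stem.casefold() in low]


def relevance_summary(n_processed: int, n_relevant: int) -> dict:
    """Relevant-share summary: percent = 100 * relevant / processed,
    round-half-even to 2 decimals."""
    pct = percent(n_relevant, n_processed, 2) if n_processed else None
    return {"n_processed": n_processed, "n_relevant": n_relevant, "percent": pct}


def survey(
    corpus_dir: str | Path,
    symbols: Sequence[str],
    mapping_path: str | Path | None = None,
    keywords: KeywordSet | Sequence[str] = DEFAULT_KEYWORDS,
    strict_absent: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Literature-relevance survey of a gene list against a corpus.

    Symbols are deduped and mapped to gene IDs (identity mapping when
    ``mapping_path`` is None); each mapped gene's ``<gene_id>.txt`` (or
    ``.html``) document is searched for keyword stems.  Unmapped genes
    are excluded from denominators; genes without documents are excluded
    and logged unless ``strict_absent``, in which case they count as
    processed but irrelevant.

    Returns the per-gene relevance table and the summary dict
    (n_processed, n_relevant, percent).
    """
    corpus_dir = Path(corpus_dir)
    if not corpus_dir.is_dir():
        raise IOError(f"corpus directory not readable: {corpus_dir}")
    unique = dedupe_genes(symbols)
    if mapping_path is not None:
        ids, unmapped = map_symbols(unique, mapping_path)
        mapped_pairs = [(s, i) for s, i in zip(
            [u for u in unique if u not in set(unmapped)], ids
        )]
    else:
        unmapped = []
        mapped_pairs = [(s, s) for s in unique]

    rows = []
    n_processed = n_relevant = 0
    for symbol, gene_id in mapped_pairs:
        doc = corpus_dir / f"{gene_id}.txt"
        if not doc.exists():
            doc = corpus_dir / f"{gene_id}.html"
        if not doc.exists():
            if strict_absent:
                n_processed += 1
                rows.append((symbol, gene_id, False, ""))
            else:
                logger.info("no document for gene %s (%s); excluded", symbol, gene_id)
                rows.append((symbol, gene_id, None, ""))
            continue
        stems = match_keywords(doc.read_text(), keywords)
        n_processed += 1
        if stems:
            n_relevant += 1
        rows.append((symbol, gene_id, bool(stems), ",".join(stems)))
    for symbol in unmapped:
        rows.append((symbol, "", None, ""))

    table = pd.DataFrame(
        rows, columns=["symbol", "gene_id", "relevant", "matched_stems"]
    )
    return table, relevance_summary(n_processed, n_relevant)
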