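"""Splice-junction extraction from spliced alignments.

A splice junction is the intron interval an aligner encodes as an ``N``
operation in a read's CIGAR string.  This module walks CIGAR strings to
pull those intervals out of a SAM file, deduplicates them into distinct
junctions with read-support tallies, classifies each junction's
donor/acceptor dinucleotides against the genome (canonical GT-AG and the
minor GC-AG / AT-AC classes, on either strand), and assigns junctions to
annotated genes by interval overlap.

Coordinates are 0-based half-open throughout; GTF input (1-based,
inclusive) is converted at the reader boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

__all__ = [
    "AlignedRead",
    "SpliceJunction",
    "GeneSpan",
    "parse_cigar",
    "read_junctions",
    "extract_junctions",
    "classify_motif",
    "classify_motif_pair",
    "junctions_per_gene",
    "read_gene_spans",
    "write_junction_table",
    "read_junction_table",
    "DEFAULT_MIN_ANCHOR",
]

DEFAULT_MIN_ANCHOR = 8

# CIGAR ops that consume the reference.
_REF_OPS = set("MDN=X")
_VALID_OPS = set("MIDNSH=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# (donor, acceptor) dinucleotides in forward-genome letters -> (class, strand).
_MOTIF_TABLE = {
    ("GT", "AG"): ("GT-AG", "+"),
    ("CT", "AC"): ("GT-AG", "-"),
    ("GC", "AG"): ("GC-AG", "+"),
    ("CT", "GC"): ("GC-AG", "-"),
    ("AT", "AC"): ("AT-AC", "+"),
    ("GT", "AT"): ("AT-AC", "-"),
}


@dataclass(frozen=True)
class AlignedRead:
    """Minimal spliced-alignment record sufficient for junction detection."""

    read_id: str
    reference_name: str
    pos: int  # 0-based leftmost aligned reference position
    cigar: tuple[tuple[str, int], ...]
    is_unmapped: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    strand_tag: str | None = None  # XS-style strand-of-transcription tag

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position for read {self.read_id!r}")
        for op, length in self.cigar:
            if op not in _VALID_OPS or length < 1:
                raise ValueError(
                    f"invalid CIGAR op {length}{op} in read {self.read_id!r}"
                )


@dataclass
class SpliceJunction:
    """A distinct intron interval with strand, motif class, and read support."""

    chrom: str
    intron_start: int  # 0-based inclusive
    intron_end: int  # exclusive
    strand: str = "."  # '+', '-', or '.' (unknown)
    read_support: int = 1
    motif_class: str = "other"
    donor: str = ""
    acceptor: str = ""

    def __post_init__(self) -> None:
        if self.intron_start >= self.intron_end:
            raise ValueError(
                f"degenerate junction {self.chrom}:{self.intron_start}-{self.intron_end}"
            )

    @property
    def intron_length(self) -> int:
        return self.intron_end - self.intron_start

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.intron_start, self.intron_end, self.strand)

    @property
    def interval_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.intron_start, self.intron_end)


@dataclass(frozen=True)
class GeneSpan:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"degenerate gene span for {self.gene_id!r}")


def parse_cigar(cigar: str, read_id: str = "?") -> tuple[tuple[str, int], ...]:
    """Parse a CIGAR string into (op, length) tuples.

    Raises ``ValueError`` naming the read on malformed tokens.
    """
    if cigar == "*":
        return ()
    ops = []
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR {cigar!r} in read {read_id!r}")
        ops.append((m.group(2), int(m.group(1))))
        pos = m.end()
    if pos != len(cigar) or not ops:
        raise ValueError(f"malformed CIGAR {cigar!r} in read {read_id!r}")
    return tuple(ops)


def read_junctions(
    read: AlignedRead | tuple[int, Sequence[tuple[str, int]]],
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> list[tuple[int, int]]:
    """Intron intervals implied by one read's CIGAR.

    The reference cursor advances through M/D/N/=/X operations only.  An
    N op yields a junction iff the aligned reference blocks flanking it
    (maximal runs of reference-consuming non-N ops) are each at least
    ``min_anchor`` bases long.  Intervals are 0-based half-open.
    """
    if min_anchor < 1:
        raise ValueError("min_anchor must be >= 1")
    if isinstance(read, AlignedRead):
        if read.is_unmapped:
            return []
        pos, cigar = read.pos, read.cigar
    else:
        pos, cigar = read

    # Segment the reference walk at N ops: [(block_len), N, (block_len), ...]
    junctions: list[tuple[int, int]] = []
    cursor = pos
    block_len = 0  # reference length of current aligned block
    pending: tuple[int, int] | None = None  # junction awaiting right anchor
    for op, length in cigar:
        if op == "N":
            if pending is not None and block_len >= min_anchor:
                junctions.append(pending)
            pending = None
            if block_len >= min_anchor:
                pending = (cursor, cursor + length)
            cursor += length
            block_len = 0
        elif op in _REF_OPS:  # M, D, =, X
            cursor += length
            block_len += length
        # I, S, H consume no reference
    if pending is not None and block_len >= min_anchor:
        junctions.append(pending)
    return junctions


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[start:end) as an uppercase string from any of the
    supported genome containers (pyfaidx.Fasta, mapping of strings, or an
    object with a .fetch method)."""
    if hasattr(genome, "fetch"):
        seq = genome.fetch(chrom, start, end)
    else:
        record = genome[chrom]
        seq = record[start:end]
        if hasattr(seq, "seq"):  # pyfaidx.Sequence
            seq = seq.seq
        elif isinstance(seq, (bytes, bytearray)):
            seq = seq.decode()
    return str(seq).upper()


def _chrom_length(genome, chrom: str) -> int | None:
    if hasattr(genome, "length"):
        try:
            return genome.length(chrom)
        except TypeError:
            pass
    try:
        return len(genome[chrom])
    except Exception:
        return None


def classify_motif_pair(donor: str, acceptor: str) -> tuple[str, str]:
    """Motif class and inferred strand for a (donor, acceptor) dinucleotide
    pair given in forward-genome letters.  Case-insensitive; unrecognised
    pairs are ('other', '.')."""
    return _MOTIF_TABLE.get((donor.upper(), acceptor.upper()), ("other", "."))


def classify_motif(genome, junction: SpliceJunction) -> tuple[str, str]:
    """Classify a junction's splice-site motif against the genome.

    Returns (motif_class, strand) and fills the junction's motif fields.
    The donor dinucleotide is genome[start:start+2), the acceptor
    genome[end-2:end); minus-strand motifs appear reverse-complemented in
    forward-genome letters (canonical GT..AG reads CT..AC).
    """
    if junction.intron_length < 4:
        raise ValueError("intron too short to carry splice-site motifs")
    length = _chrom_length(genome, junction.chrom)
    if junction.intron_start < 0 or (length is not None and junction.intron_end > length):
        raise ValueError(
            f"junction {junction.chrom}:{junction.intron_start}-{junction.intron_end} "
            f"outside chromosome bounds"
        )
    donor = _fetch(genome, junction.chrom, junction.intron_start, junction.intron_start + 2)
    acceptor = _fetch(genome, junction.chrom, junction.intron_end - 2, junction.intron_end)
    motif, strand = classify_motif_pair(donor, acceptor)
    junction.donor, junction.acceptor = donor, acceptor
    junction.motif_class = motif
    if motif != "other":
        junction.strand = strand
    elif junction.strand not in ("+", "-"):
        junction.strand = "."
    return motif, junction.strand


def iter_sam_reads(sam_path: str | Path) -> Iterable[AlignedRead]:
    """Yield mapped primary/secondary/supplementary records as AlignedRead."""
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            cigar = ()
            if rec.cigartuples:
                cigar = tuple(
                    ("MIDNSHP=X"[op], length) for op, length in rec.cigartuples
                )
            yield AlignedRead(
                read_id=rec.query_name,
                reference_name=rec.reference_name or "*",
                pos=max(rec.reference_start, 0),
                cigar=cigar,
                is_unmapped=rec.is_unmapped,
                is_secondary=rec.is_secondary,
                is_supplementary=rec.is_supplementary,
                strand_tag=rec.get_tag("XS") if rec.has_tag("XS") else None,
            )


def extract_junctions(
    sam_path: str | Path,
    genome,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> list[SpliceJunction]:
    """Extract the distinct splice junctions of a SAM file.

    Junctions are deduplicated on (chrom, intron_start, intron_end);
    ``read_support`` counts distinct mapped, primary, non-supplementary
    records emitting the interval.  Motif class and strand are filled
    from the genome.  The result is sorted by coordinate.
    """
    support: dict[tuple[str, int, int], int] = {}
    strand_tags: dict[tuple[str, int, int], str] = {}
    for read in iter_sam_reads(sam_path):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        for start, end in read_junctions(read, min_anchor=min_anchor):
            key = (read.reference_name, start, end)
            support[key] = support.get(key, 0) + 1
            if read.strand_tag in ("+", "-"):
                strand_tags.setdefault(key, read.strand_tag)

    junctions = []
    for (chrom, start, end), n in sorted(support.items()):
        if _chrom_length(genome, chrom) is None and not hasattr(genome, "fetch"):
            raise KeyError(f"reference {chrom!r} absent from genome")
        j = SpliceJunction(chrom, start, end, read_support=n)
        try:
            classify_motif(genome, j)
        except KeyError:
            raise KeyError(f"reference {chrom!r} absent from genome") from None
        if j.motif_class == "other" and strand_tags.get((chrom, start, end)):
            j.strand = strand_tags[(chrom, start, end)]
        junctions.append(j)
    return junctions


def read_gene_spans(gtf_path: str | Path) -> list[GeneSpan]:
    """Gene spans from a GTF: explicit ``gene`` features when present,
    otherwise the union of each gene_id's exons.  Converts to 0-based
    half-open coordinates."""
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    spans = []
    genes = list(db.features_of_type("gene"))
    if genes:
        for g in genes:
            spans.append(
                GeneSpan(g.attributes["gene_id"][0], g.seqid, g.start - 1, g.end, g.strand)
            )
    else:
        by_gene: dict[str, list] = {}
        for ex in db.features_of_type("exon"):
            by_gene.setdefault(ex.attributes["gene_id"][0], []).append(ex)
        for gene_id, exons in by_gene.items():
            spans.append(
                GeneSpan(
                    gene_id,
                    exons[0].seqid,
                    min(e.start for e in exons) - 1,
                    max(e.end for e in exons),
                    exons[0].strand,
                )
            )
    spans.sort(key=lambda s: (s.chrom, s.start, s.gene_id))
    return spans


def junctions_per_gene(
    junctions: Sequence[SpliceJunction],
    gene_spans: Sequence[GeneSpan],
) -> pd.DataFrame:
    """Per-gene junction tallies, both variants.

    ``distinct`` counts junction keys whose intron interval overlaps the
    gene span; ``reads`` sums their read support.  A junction overlapping
    k genes contributes to all k; genes with no junctions appear with 0.
    """
    trees: dict[str, IntervalTree] = {}
    for span in gene_spans:
        trees.setdefault(span.chrom, IntervalTree()).addi(span.start, span.end, span.gene_id)

    distinct = {s.gene_id: 0 for s in gene_spans}
    reads = {s.gene_id: 0 for s in gene_spans}
    for j in junctions:
        tree = trees.get(j.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(j.intron_start, j.intron_end):
            distinct[hit.data] += 1
            reads[hit.data] += j.read_support
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in gene_spans],
            "distinct": [distinct[s.gene_id] for s in gene_spans],
            "reads": [reads[s.gene_id] for s in gene_spans],
        }
    )


_TABLE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "motif_class",
    "intron_length",
    "genes",
]


def write_junction_table(
    junctions: Sequence[SpliceJunction],
    path: str | Path,
    gene_map: Mapping[tuple[str, int, int], Sequence[str]] | None = None,
) -> None:
    """Write junctions as a BED6+3 TSV (score = read support)."""
    rows = []
    for i, j in enumerate(junctions):
        genes = ",".join(gene_map.get(j.interval_key, [])) if gene_map else "."
        rows.append(
            (
                j.chrom,
                j.intron_start,
                j.intron_end,
                f"JUNC{i + 1:06d}",
                j.read_support,
                j.strand,
                j.motif_class,
                j.intron_length,
                genes or ".",
            )
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_junction_table(path: str | Path) -> list[SpliceJunction]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    junctions = []
    for row in df.itertuples(index=False):
        junctions.append(
            SpliceJunction(
                chrom=row.chrom,
                intron_start=int(row.start),
                intron_end=int(row.end),
                strand=row.strand,
                read_support=int(row.score),
                motif_class=row.motif_class,
            )
        )
    return junctions
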