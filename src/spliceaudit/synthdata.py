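"""Synthetic RNA-seq fixtures with planted ground truth.

Generates every input the pipeline consumes — a random genome, a gene
annotation whose introns carry genuine GT..AG splice motifs (CT..AC in
forward-genome letters on the minus strand), spliced single-end
alignments over those introns plus labelled artifact junctions, two-arm
transcript count matrices with planted differential-expression /
unique-expression / arm-exclusive structure, matching per-transcript
DE-statistics tables, and a per-gene text corpus with planted
disease-keyword stems.

Artifact junction classes mirror the failure modes confidence-based
junction filters are meant to remove:

* ``noncanonical_motif`` — splice-site dinucleotides that are not
  GT-AG/CT-AC (written into the genome so classification is guaranteed);
* ``ultralong_intron`` — an intron longer than 100 kb spanning two gene
  loci on the same chromosome;
* ``boundary_shift`` — a real junction with its donor or acceptor
  displaced by 3–30 bases into the exon or intron (syntactically valid,
  mis-positioned);
* ``singleton_support`` — a junction spanned by exactly one read.

Every junction emitted in the SAM has exactly one row in the truth
table, recording label, class, planted motif and exact read support, so
downstream modules can be tested against exact bookkeeping.  All stages
draw from their own RNG stream seeded from (seed, stage index), so each
stage is independently reproducible and outputs are byte-identical for a
fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .junctions import classify_motif_pair

__all__ = [
    "SimConfig",
    "Genome",
    "Gene",
    "Annotation",
    "make_genome",
    "make_annotation",
    "make_alignments",
    "make_expression",
    "make_corpus",
    "simulate",
    "load_config",
]

SPURIOUS_CLASSES = (
    "noncanonical_motif",
    "ultralong_intron",
    "boundary_shift",
    "singleton_support",
)

_BASES = np.frombuffer(b"ACGT", dtype="u1")
_COMP = {65: 84, 67: 71, 71: 67, 84: 65}

# Stage offsets for per-stage RNG streams.
_STAGE_GENOME, _STAGE_ANNOT, _STAGE_ALIGN, _STAGE_EXPR, _STAGE_CORPUS = range(5)


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults emulate the shape of a two-group bulk brain RNA-seq study
    (8 samples per group, ~10% of junction-bearing evidence spurious, a
    ~15% literature-relevant gene fraction) at a size small enough to
    regenerate in seconds.
    """

    seed: int = 0
    # genome / annotation
    n_chroms: int = 2
    chrom_length: int = 400_000
    n_genes: int = 20
    exons_per_gene: int = 3
    exon_length: int = 200
    intron_length_log_mean: float = 7.0  # log-normal, median ~1.1 kb
    intron_length_log_sd: float = 0.6
    # alignments
    read_length: int = 100
    depth_per_junction: int = 10
    spurious_fraction: float = 0.15  # share of distinct junctions that are artifacts
    spurious_class_weights: dict = field(
        default_factory=lambda: {c: 0.25 for c in SPURIOUS_CLASSES}
    )
    spurious_read_support: int = 2  # reads per non-singleton artifact junction
    min_anchor: int = 8
    # expression
    n_transcripts: int = 300
    n_samples_per_group: int = 8
    de_fraction: float = 0.10
    de_up_share: float = 0.75  # up-regulated share of planted DE
    unique_fraction: float = 0.05
    low_expression_fraction: float = 0.05
    arm_exclusive_fraction: float = 0.05
    novel_gene_fraction: float = 0.20  # MSTRG-prefixed novel loci
    nb_mean_low: float = 20.0
    nb_mean_high: float = 200.0
    nb_dispersion: float = 0.1
    log2fc: float = 2.0
    # corpus
    corpus_relevant_fraction: float = 0.15

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        props = {
            "spurious_fraction": self.spurious_fraction,
            "de_fraction": self.de_fraction,
            "unique_fraction": self.unique_fraction,
            "low_expression_fraction": self.low_expression_fraction,
            "arm_exclusive_fraction": self.arm_exclusive_fraction,
            "novel_gene_fraction": self.novel_gene_fraction,
            "corpus_relevant_fraction": self.corpus_relevant_fraction,
            "de_up_share": self.de_up_share,
        }
        for name, value in props.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.de_fraction + self.unique_fraction > 1.0:
            raise ValueError("de_fraction + unique_fraction must not exceed 1")
        if (
            self.de_fraction + self.unique_fraction + self.low_expression_fraction
        ) > 1.0:
            raise ValueError("planted expression fractions exceed 1")
        if set(self.spurious_class_weights) - set(SPURIOUS_CLASSES):
            raise ValueError(f"unknown spurious classes: {self.spurious_class_weights}")
        total = sum(self.spurious_class_weights.values())
        if self.spurious_fraction > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"spurious_class_weights sum to {total}, expected 1")
        if self.chrom_length < 10_000:
            raise ValueError("chrom_length must be >= 10,000")
        if self.n_samples_per_group < 2:
            raise ValueError("n_samples_per_group must be >= 2")
        if self.read_length < 2 * self.min_anchor + 1:
            raise ValueError(
                f"read_length {self.read_length} too short to hold two "
                f">= {self.min_anchor}-base anchors"
            )
        if self.exons_per_gene < 2:
            raise ValueError("exons_per_gene must be >= 2 (genes must be spliced)")
        if self.spurious_fraction >= 1.0:
            raise ValueError("spurious_fraction must be < 1")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stage)])


class Genome:
    """In-memory genome: chromosome name -> mutable base array."""

    def __init__(self, chroms: dict[str, bytearray]):
        self.chroms = chroms

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def names(self) -> list[str]:
        return list(self.chroms)

    def length(self, chrom: str) -> int:
        return len(self.chroms[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.chroms[chrom][start:end].decode()

    def write_bases(self, chrom: str, pos: int, bases: str) -> None:
        self.chroms[chrom][pos : pos + len(bases)] = bases.encode()

    def write(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w", newline="\n") as fh:
            for name, seq in self.chroms.items():
                fh.write(f">{name}\n")
                text = seq.decode()
                for i in range(0, len(text), width):
                    fh.write(text[i : i + width] + "\n")


@dataclass
class Gene:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class Annotation:
    genes: list[Gene]

    def write_gtf(self, path: str | Path) -> None:
        """GTF2.2, 1-based inclusive, with gene/transcript/exon features."""
        with open(path, "w", newline="\n") as fh:
            for g in self.genes:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.transcript_id}";'
                fh.write(
                    "\t".join(
                        [g.chrom, "spliceaudit", "gene", str(g.start + 1),
                         str(g.end), ".", g.strand, ".", f'gene_id "{g.gene_id}";']
                    )
                    + "\n"
                )
                fh.write(
                    "\t".join(
                        [g.chrom, "spliceaudit", "transcript", str(g.start + 1),
                         str(g.end), ".", g.strand, ".", attrs]
                    )
                    + "\n"
                )
                for i, (s, e) in enumerate(g.exons, 1):
                    fh.write(
                        "\t".join(
                            [g.chrom, "spliceaudit", "exon", str(s + 1), str(e),
                             ".", g.strand, ".", attrs + f' exon_number "{i}";']
                        )
                        + "\n"
                    )

    def true_junctions(self) -> list[tuple[str, int, int, str]]:
        out = []
        for g in self.genes:
            for s, e in g.introns:
                out.append((g.chrom, s, e, g.strand))
        return out


def make_genome(config: SimConfig) -> Genome:
    """Random uppercase A/C/G/T genome, deterministic for a fixed seed."""
    rng = config.rng(_STAGE_GENOME)
    chroms: dict[str, bytearray] = {}
    for i in range(config.n_chroms):
        idx = rng.integers(0, 4, size=config.chrom_length)
        chroms[f"chr{i + 1}"] = bytearray(_BASES[idx].tobytes())
    return Genome(chroms)


def _sample_introns(rng, config: SimConfig, max_total: int) -> list[int] | None:
    n = config.exons_per_gene - 1
    for _ in range(20):
        lengths = rng.lognormal(
            config.intron_length_log_mean, config.intron_length_log_sd, size=n
        )
        lengths = np.maximum(lengths.astype(int), 60)
        if lengths.sum() <= max_total:
            return [int(x) for x in lengths]
    return None


def make_annotation(genome: Genome, config: SimConfig) -> Annotation:
    """Place spliced genes on the genome and plant true splice motifs.

    Genes are laid out in evenly spaced slots per chromosome; each true
    intron's donor/acceptor dinucleotides are written into the genome as
    GT/AG on the transcribed strand (CT/AC in forward letters for
    minus-strand genes).  Raises a sizing error when genes cannot be
    packed into ``chrom_length``.
    """
    rng = config.rng(_STAGE_ANNOT)
    margin = 1_000
    per_chrom = [
        len([g for g in range(config.n_genes) if g % config.n_chroms == c])
        for c in range(config.n_chroms)
    ]
    genes: list[Gene] = []
    for c, chrom in enumerate(genome.names()):
        n_here = per_chrom[c]
        if n_here == 0:
            continue
        usable = config.chrom_length - 2 * margin
        slot = usable // n_here
        exonic = config.exons_per_gene * config.exon_length
        if slot <= exonic + 60 * (config.exons_per_gene - 1) + 100:
            raise ValueError(
                f"cannot pack {n_here} genes into {chrom}: need > "
                f"{exonic + 160} bases per gene, slot is {slot}"
            )
        for k in range(n_here):
            gene_idx = c + k * config.n_chroms
            slot_start = margin + k * slot
            introns = _sample_introns(rng, config, slot - exonic - 200)
            if introns is None:
                raise ValueError(
                    f"cannot fit sampled introns of gene {gene_idx} into a "
                    f"{slot}-base slot on {chrom}"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = slot_start + int(rng.integers(0, 100))
            for i in range(config.exons_per_gene):
                exons.append((pos, pos + config.exon_length))
                pos += config.exon_length
                if i < config.exons_per_gene - 1:
                    pos += introns[i]
            gid = f"GENE{gene_idx + 1:04d}"
            gene = Gene(gid, gid + ".1", chrom, strand, exons)
            for s, e in gene.introns:
                if strand == "+":
                    genome.write_bases(chrom, s, "GT")
                    genome.write_bases(chrom, e - 2, "AG")
                else:
                    genome.write_bases(chrom, s, "CT")
                    genome.write_bases(chrom, e - 2, "AC")
            genes.append(gene)
    genes.sort(key=lambda g: (g.chrom, g.start))
    return Annotation(genes)


def _largest_remainder(weights: dict[str, float], total: int) -> dict[str, int]:
    """Deterministic integer allocation of ``total`` across classes."""
    raw = {c: weights.get(c, 0.0) * total for c in SPURIOUS_CLASSES}
    out = {c: int(math.floor(v)) for c, v in raw.items()}
    rest = total - sum(out.values())
    order = sorted(SPURIOUS_CLASSES, key=lambda c: (-(raw[c] - out[c]), c))
    for c in order[:rest]:
        out[c] += 1
    return out


@dataclass
class _PlannedJunction:
    chrom: str
    start: int
    end: int
    strand: str
    label: str  # 'true' | 'spurious'
    spurious_class: str  # '' for true junctions
    support: int


def _place_intronic(rng, intron: tuple[int, int], used: set) -> tuple[int, int] | None:
    """A sub-interval strictly inside a true intron, clear of its motifs."""
    s0, e0 = intron
    if e0 - s0 < 30:
        return None
    for _ in range(30):
        d1 = int(rng.integers(4, max(5, min(21, (e0 - s0) // 3))))
        d2 = int(rng.integers(4, max(5, min(21, (e0 - s0) // 3))))
        ns, ne = s0 + d1, e0 - d2
        if ne - ns >= 10 and (ns, ne) not in used:
            return ns, ne
    return None


def make_alignments(
    genome: Genome, annotation: Annotation, config: SimConfig
) -> tuple[list[tuple], pd.DataFrame]:
    """Spliced single-end reads over true and artifact junctions.

    Returns (records, truth): ``records`` are SAM record tuples
    (qname, flag, chrom, pos0, mapq, cigar, seq) in emission order, and
    ``truth`` has one row per distinct junction in the SAM with its
    label, artifact class, planted motif and exact read support.
    """
    rng = config.rng(_STAGE_ALIGN)
    true = annotation.true_junctions()
    n_true = len(true)
    used: set[tuple[int, int]] = {(s, e) for _, s, e, _ in true}

    f = config.spurious_fraction
    n_spur = int(round(f / (1.0 - f) * n_true)) if f > 0 else 0
    alloc = _largest_remainder(config.spurious_class_weights, n_spur)

    genes = annotation.genes
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    # Hosts for intronic artifact placements: shuffled true introns.
    host_pool = [
        (g.chrom, intron) for g in genes for intron in g.introns
    ]
    host_order = rng.permutation(len(host_pool))
    host_iter = iter(host_order)

    def next_host() -> tuple[str, tuple[int, int]]:
        for idx in host_iter:
            return host_pool[int(idx)]
        raise ValueError(
            "not enough host introns to place artifact junctions; lower "
            "spurious_fraction or raise n_genes/exons_per_gene"
        )

    planned: list[_PlannedJunction] = [
        _PlannedJunction(c, s, e, st, "true", "", config.depth_per_junction)
        for c, s, e, st in true
    ]

    # noncanonical_motif: intronic placement with planted CC..GG boundaries.
    for _ in range(alloc["noncanonical_motif"]):
        placed = None
        while placed is None:
            chrom, intron = next_host()
            placed = _place_intronic(rng, intron, used)
        ns, ne = placed
        genome.write_bases(chrom, ns, "CC")
        genome.write_bases(chrom, ne - 2, "GG")
        used.add((ns, ne))
        planned.append(
            _PlannedJunction(chrom, ns, ne, ".", "spurious", "noncanonical_motif",
                             config.spurious_read_support)
        )

    # ultralong_intron: >100 kb junction spanning two gene loci.
    for i in range(alloc["ultralong_intron"]):
        chrom = max(by_chrom, key=lambda c: by_chrom[c][-1].end - by_chrom[c][0].start)
        first, last = by_chrom[chrom][0], by_chrom[chrom][-1]
        ns = first.exons[0][1] - int(rng.integers(20, 120)) - 2 * i
        ne = last.exons[-1][0] + int(rng.integers(20, 120)) + 2 * i
        if ne - ns <= 100_000:
            raise ValueError(
                "chromosome layout cannot host a >100 kb cross-locus intron; "
                "increase chrom_length or genes per chromosome"
            )
        while (ns, ne) in used:
            ne += 1
        used.add((ns, ne))
        planned.append(
            _PlannedJunction(chrom, ns, ne, ".", "spurious", "ultralong_intron",
                             config.spurious_read_support)
        )

    # boundary_shift: a true junction with one edge displaced 3..30 bases.
    true_order = rng.permutation(n_true)
    shift_iter = iter(true_order)
    for _ in range(alloc["boundary_shift"]):
        placed = None
        for idx in shift_iter:
            chrom, s, e, _ = true[int(idx)]
            for _try in range(20):
                delta = int(rng.integers(3, 31)) * (1 if rng.random() < 0.5 else -1)
                if rng.random() < 0.5:
                    ns, ne = s + delta, e
                else:
                    ns, ne = s, e + delta
                if (
                    ns >= config.min_anchor
                    and ne <= genome.length(chrom) - config.min_anchor
                    and ne - ns >= 10
                    and (ns, ne) not in used
                ):
                    placed = (chrom, ns, ne)
                    break
            if placed:
                break
        if placed is None:
            raise ValueError("could not place boundary_shift artifacts")
        used.add(placed[1:])
        planned.append(
            _PlannedJunction(*placed, ".", "spurious", "boundary_shift",
                             config.spurious_read_support)
        )

    # singleton_support: intronic placement, genome motif left as sampled.
    for _ in range(alloc["singleton_support"]):
        placed = None
        while placed is None:
            chrom, intron = next_host()
            placed = _place_intronic(rng, intron, used)
        ns, ne = placed
        used.add((ns, ne))
        planned.append(
            _PlannedJunction(chrom, ns, ne, ".", "spurious", "singleton_support", 1)
        )

    # Resolve planted motifs and strands from the (final) genome.
    truth_rows = []
    for p in planned:
        donor = genome.fetch(p.chrom, p.start, p.start + 2)
        acceptor = genome.fetch(p.chrom, p.end - 2, p.end)
        motif_class, strand = classify_motif_pair(donor, acceptor)
        truth_rows.append(
            {
                "chrom": p.chrom,
                "intron_start": p.start,
                "intron_end": p.end,
                "strand": strand,
                "label": p.label,
                "spurious_class": p.spurious_class or "none",
                "donor": donor,
                "acceptor": acceptor,
                "motif_class": motif_class,
                "support": p.support,
            }
        )
    truth = pd.DataFrame(truth_rows).sort_values(
        ["chrom", "intron_start", "intron_end"], ignore_index=True
    )

    # Emit reads.
    records: list[tuple] = []
    serial = 0
    order = truth.itertuples(index=False)
    for row in order:
        chrom_len = genome.length(row.chrom)
        for _r in range(row.support):
            serial += 1
            lo, hi = config.min_anchor, config.read_length - config.min_anchor
            a = int(rng.integers(lo, hi + 1))
            a = min(a, row.intron_start)  # keep pos >= 0
            b = config.read_length - a
            if row.intron_end + b > chrom_len:
                b = chrom_len - row.intron_end
                a = config.read_length - b
            pos = row.intron_start - a
            seq = genome.fetch(row.chrom, pos, row.intron_start) + genome.fetch(
                row.chrom, row.intron_end, row.intron_end + b
            )
            cigar = f"{a}M{row.intron_end - row.intron_start}N{b}M"
            tag = "t" if row.label == "true" else "s"
            records.append(
                (f"{tag}{serial:06d}", 0, row.chrom, pos, 60, cigar, seq)
            )
    # Junction-free reads, one per gene over its first exon.
    for g in genes:
        serial += 1
        s = g.exons[0][0]
        length = min(config.read_length, g.exons[0][1] - s)
        records.append(
            (f"p{serial:06d}", 0, g.chrom, s, 60,
             f"{length}M", genome.fetch(g.chrom, s, s + length))
        )
    return records, truth


def write_sam(
    records: Sequence[tuple], genome: Genome, path: str | Path
) -> None:
    """Write SAM v1 text with @HD/@SQ header, QUAL omitted."""
    with open(path, "w", newline="\n") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name in genome.names():
            fh.write(f"@SQ\tSN:{name}\tLN:{genome.length(name)}\n")
        for qname, flag, chrom, pos, mapq, cigar, seq in records:
            fh.write(
                f"{qname}\t{flag}\t{chrom}\t{pos + 1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*\n"
            )


def make_expression(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Two-arm count tables, DE-statistics tables and expression truth.

    Counts are negative-binomial with per-transcript means; planted DE
    transcripts carry a fixed log2 fold-change (default ±2) applied to
    the AD group; planted unique transcripts are zeroed in one group;
    low-expression plants are all-zero rows; arm-exclusive transcripts
    appear in exactly one arm's table at coordinates absent from the
    other.  Planted raw p-values are constructed, not fitted: nulls are
    uniform on [0.05, 1), planted DE around 1e-6, so threshold logic is
    exercised with exact expected outcomes.
    """
    rng = config.rng(_STAGE_EXPR)
    n = config.n_transcripts
    n_ctrl = n_ad = config.n_samples_per_group
    ctrl_cols = [f"ctrl{i + 1}" for i in range(n_ctrl)]
    ad_cols = [f"ad{i + 1}" for i in range(n_ad)]

    n_unique = int(round(config.unique_fraction * n))
    n_low = int(round(config.low_expression_fraction * n))
    n_de = int(round(config.de_fraction * n))
    n_up = int(round(config.de_up_share * n_de))
    n_excl = int(round(config.arm_exclusive_fraction * n))

    order = rng.permutation(n)
    uniq_idx = set(order[:n_unique].tolist())
    low_idx = set(order[n_unique : n_unique + n_low].tolist())
    de_idx = order[n_unique + n_low : n_unique + n_low + n_de].tolist()
    up_idx = set(de_idx[:n_up])
    down_idx = set(de_idx[n_up:])
    uniq_list = sorted(uniq_idx)
    ad_only_idx = set(uniq_list[: len(uniq_list) // 2 + len(uniq_list) % 2])
    ctrl_only_idx = uniq_idx - ad_only_idx

    excl_order = rng.permutation(n)
    excl = [i for i in excl_order.tolist()][:n_excl]
    a_only_idx = set(excl[: n_excl // 2])
    b_only_idx = set(excl[n_excl // 2 :])

    n_novel = int(round(config.novel_gene_fraction * n))
    novel_idx = set(rng.permutation(n)[:n_novel].tolist())

    means = rng.uniform(config.nb_mean_low, config.nb_mean_high, size=n)

    def nb(mean: np.ndarray, size) -> np.ndarray:
        # NB with dispersion phi: var = mu + phi*mu^2.
        phi = config.nb_dispersion
        r = 1.0 / phi
        p = r / (r + mean)
        return rng.negative_binomial(r, p, size=size)

    rows = []
    truth_rows = []
    slot = 2_000
    for i in range(n):
        tid = f"TX{i + 1:05d}"
        if i in novel_idx:
            gene = f"MSTRG.{i + 1}"
        else:
            gene = f"GENE{i + 1:04d}"
        chrom = f"chrE{i % 4 + 1}"
        start = 1_000 + (i // 4) * slot
        end = start + int(rng.integers(500, slot - 100))
        strand = "+" if rng.random() < 0.5 else "-"

        mu = means[i]
        ctrl = nb(np.full(n_ctrl, mu), n_ctrl)
        fc = 1.0
        status = "null"
        if i in up_idx:
            fc, status = 2.0 ** config.log2fc, "de_up"
        elif i in down_idx:
            fc, status = 2.0 ** (-config.log2fc), "de_down"
        ad = nb(np.full(n_ad, mu * fc), n_ad)

        uniqueness = "both"
        if i in low_idx:
            ctrl[:] = 0
            ad[:] = 0
            uniqueness = "neither"
            status = "null"
        elif i in ad_only_idx:
            ctrl[:] = 0
            ad[0] = max(ad[0], 1)
            uniqueness = "ad_only"
            status = "null"
        elif i in ctrl_only_idx:
            ad[:] = 0
            ctrl[0] = max(ctrl[0], 1)
            uniqueness = "control_only"
            status = "null"
        else:
            ctrl[0] = max(ctrl[0], 1)
            ad[0] = max(ad[0], 1)

        if status == "de_up":
            lfc = config.log2fc + float(rng.normal(0, 0.1))
            pval = 10 ** float(rng.uniform(-7, -5))
        elif status == "de_down":
            lfc = -config.log2fc + float(rng.normal(0, 0.1))
            pval = 10 ** float(rng.uniform(-7, -5))
        else:
            lfc = float(rng.normal(0, 0.3))
            pval = float(rng.uniform(0.05, 1.0))

        arm = "both_arms"
        if i in a_only_idx:
            arm = "armA_only"
        elif i in b_only_idx:
            arm = "armB_only"

        rows.append(
            [tid, gene, chrom, start, end, strand]
            + ctrl.tolist()
            + ad.tolist()
            + [lfc, pval, arm]
        )
        truth_rows.append([tid, gene, status, uniqueness, arm])

    cols = ["transcript_id", "gene_id", "chrom", "start", "end", "strand"]
    table = pd.DataFrame(
        rows, columns=cols + ctrl_cols + ad_cols + ["log2FC", "pvalue", "arm"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["transcript_id", "gene_id", "status", "uniqueness", "arm"],
    )

    count_cols = cols + ctrl_cols + ad_cols
    arm_a = table[table["arm"] != "armB_only"][count_cols].reset_index(drop=True)
    arm_b = table[table["arm"] != "armA_only"][count_cols].reset_index(drop=True)
    de_cols = ["transcript_id", "log2FC", "pvalue"]
    de_a = table[table["arm"] != "armB_only"][de_cols].reset_index(drop=True)
    de_b = table[table["arm"] != "armA_only"][de_cols].reset_index(drop=True)
    return {
        "counts_armA": arm_a,
        "counts_armB": arm_b,
        "de_armA": de_a,
        "de_armB": de_b,
        "truth": truth,
        "control_samples": ctrl_cols,
        "ad_samples": ad_cols,
    }


_FILLER_WORDS = (
    "protein binding membrane kinase phosphorylation transcription factor "
    "expression regulation cellular signal pathway receptor ligand enzyme "
    "catalytic domain sequence conserved ortholog tissue liver kidney muscle "
    "epithelial development growth mitosis cycle checkpoint repair replication "
    "ribosome translation metabolic lipid glucose transport channel ion "
    "potassium sodium vesicle golgi secretion immune antibody complement "
    "interferon"
).split()

# One natural surface form per keyword stem, used when planting.
_STEM_SURFACE = {
    "Alzheimer": "Alzheimer's disease",
    "amyloid": "amyloid deposits",
    "astrocyt": "astrocytes",
    "cognit": "cognitive decline",
    "dement": "dementia",
    "memor": "memory impairment",
    "microgli": "microglial activation",
    "neurodegenerat": "neurodegeneration",
    "neuroinflamm": "neuroinflammation",
    "neuro": "neuronal loss",
    "plaque": "plaques",
    "tangl": "tangles",
    "tau": "tau pathology",
}


def _filler_paragraph(rng, n_sentences: int = 3) -> str:
    sentences = []
    for _ in range(n_sentences):
        w = [
            _FILLER_WORDS[int(i)]
            for i in rng.integers(0, len(_FILLER_WORDS), size=5)
        ]
        sentences.append(
            f"The {w[0]} {w[1]} pathway modulates {w[2]} {w[3]} in {w[4]} systems."
        )
    return " ".join(sentences)


def make_corpus(
    gene_ids: Sequence[str],
    config: SimConfig,
    keywords: Sequence[str] | None = None,
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Per-gene text documents with planted keyword stems.

    Exactly ``floor(corpus_relevant_fraction * n_genes)`` genes receive
    one to three planted stems embedded in filler text; the remainder
    contain none of the stems (verified by a self-grep, with bounded
    regeneration on accidental hits).  Returns the truth table; writes
    ``<gene_id>.txt`` files when ``outdir`` is given.
    """
    from .litsurvey import DEFAULT_KEYWORDS

    stems = list(DEFAULT_KEYWORDS) if keywords is None else list(keywords)
    if not stems:
        raise ValueError("keywords must be non-empty")
    rng = config.rng(_STAGE_CORPUS)
    gene_ids = list(gene_ids)
    n_rel = int(math.floor(config.corpus_relevant_fraction * len(gene_ids)))
    rel_idx = set(rng.permutation(len(gene_ids))[:n_rel].tolist())

    folded = [s.casefold() for s in stems]
    rows = []
    docs = {}
    for i, gid in enumerate(gene_ids):
        planted: list[str] = []
        for _attempt in range(50):
            text = _filler_paragraph(rng)
            if i in rel_idx:
                k = int(rng.integers(1, min(3, len(stems)) + 1))
                chosen = [stems[int(j)] for j in rng.choice(len(stems), size=k, replace=False)]
                extras = " ".join(
                    f"This locus has been linked to "
                    f"{_STEM_SURFACE.get(s, s)} in prior studies."
                    for s in chosen
                )
                text = text + " " + extras
                planted = sorted(set(chosen))
            low = text.casefold()
            hits = [s for s, fs in zip(stems, folded) if fs in low]
            ok = bool(hits) if i in rel_idx else not hits
            if ok:
                break
        else:
            raise RuntimeError(f"could not generate clean document for {gid}")
        docs[gid] = text
        rows.append([gid, i in rel_idx, ",".join(planted) if planted else ""])

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for gid, text in docs.items():
            (outdir / f"{gid}.txt").write_text(text + "\n", newline="\n")
    return pd.DataFrame(rows, columns=["gene_id", "relevant", "planted_stems"])


def load_config(path: str | Path) -> SimConfig:
    """Flat ``key = value`` text config mirroring SimConfig fields."""
    values: dict = {}
    weights: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key.startswith("spurious_class_weights."):
            weights[key.split(".", 1)[1]] = float(value)
            continue
        field_types = SimConfig.__dataclass_fields__
        if key not in field_types:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        ftype = field_types[key].type
        if "int" in str(ftype):
            values[key] = int(value)
        elif "float" in str(ftype):
            values[key] = float(value)
        else:
            values[key] = value
    if weights:
        values["spurious_class_weights"] = weights
    return SimConfig(**values)


def simulate(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every generator stage and write the full fixture set.

    The FASTA is written after alignment planting so artifact motifs
    written into the genome are reflected on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = make_genome(config)
    annotation = make_annotation(genome, config)
    records, junction_truth = make_alignments(genome, annotation, config)
    expr = make_expression(config)

    paths = {
        "genome": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "sam": outdir / "alignments.sam",
        "junction_truth": outdir / "junction_truth.tsv",
        "counts_armA": outdir / "counts_armA.tsv",
        "counts_armB": outdir / "counts_armB.tsv",
        "de_armA": outdir / "de_armA.tsv",
        "de_armB": outdir / "de_armB.tsv",
        "expression_truth": outdir / "expression_truth.tsv",
        "mapping": outdir / "gene_mapping.tsv",
        "corpus": outdir / "corpus",
        "corpus_truth": outdir / "corpus_truth.tsv",
    }
    genome.write(paths["genome"])
    annotation.write_gtf(paths["gtf"])
    write_sam(records, genome, paths["sam"])
    junction_truth.to_csv(paths["junction_truth"], sep="\t", index=False)
    for key in ("counts_armA", "counts_armB", "de_armA", "de_armB"):
        expr[key].to_csv(paths[key], sep="\t", index=False)
    expr["truth"].to_csv(paths["expression_truth"], sep="\t", index=False)

    # Symbol -> numeric gene ID mapping over annotated (non-novel) loci.
    symbols = sorted(
        {g for g in expr["truth"]["gene_id"] if not g.startswith("MSTRG.")}
    )
    mapping = pd.DataFrame(
        {"symbol": symbols, "gene_id": [10_000 + i for i in range(len(symbols))]}
    )
    mapping.to_csv(paths["mapping"], sep="\t", index=False)
    corpus_truth = make_corpus(
        [str(g) for g in mapping["gene_id"]], config, outdir=paths["corpus"]
    )
    corpus_truth.to_csv(paths["corpus_truth"], sep="\t", index=False)
    with open(outdir / "samples.tsv", "w", newline="\n") as fh:
        fh.write("sample\tgroup\n")
        for s in expr["control_samples"]:
            fh.write(f"{s}\tcontrol\n")
        for s in expr["ad_samples"]:
            fh.write(f"{s}\tAD\n")
    return paths
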