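# Methods

## The procedure

`spliceaudit` evaluates a two-arm RNA-seq processing design: the same
alignments analysed once as-is ("unfiltered" arm) and once after removing
reads that carry low-confidence splice junctions ("filtered" arm). The
package's job is (a) to perform the filtering and quantify what it does to
junction-level quality, and (b) to compare the downstream results of the two
arms — differential transcript expression, uniquely expressed transcripts,
and the disease-literature relevance of the implicated gene loci.

### Junctions and coordinates

A splice junction is the intron interval an aligner encodes as an `N` CIGAR
operation. All internal coordinates are 0-based half-open; GTF input (1-based
inclusive) is converted at the reader boundary and junction tables are written
0-based half-open (BED convention). A junction is emitted from a read only
when the aligned reference blocks flanking the `N` op (maximal runs of
reference-consuming non-`N` operations, so `M`, `D`, `=`, `X`) are each at
least `min_anchor` bases. `min_anchor` defaults to 8 bases — the behaviour
class of standard junction-extraction tools — and is configurable everywhere
it appears. Read support counts distinct mapped, primary, non-supplementary
records; secondary and supplementary records never contribute support, while
duplicate-flagged records do (support measures distinct alignment evidence).

Motif classification reads the donor dinucleotide at `[start, start+2)` and
the acceptor at `[end-2, end)`. Forward-letter pairs map to classes and
strands: `GT..AG`/`CT..AC` → `GT-AG` on `+`/`-`, likewise `GC-AG` and
`AT-AC`; everything else is `other` with unknown strand, falling back to an
alignment strand tag when present. Comparison is case-insensitive.

### QC metrics

The report carries: number of distinct junctions; median read support;
percent of junctions with support ≥ 5 (inclusive); percent with canonical
`GT-AG` motif; median intron length; percent of introns strictly longer than
100,000 bases; and mean junctions per annotated gene in two variants —
distinct junction keys and summed junction reads — averaged over *every*
annotated gene, including zero-junction genes (this makes the mean stable in
the annotation; a junction overlapping k gene spans counts for all k).
Medians are the standard mean-of-middle-two for even n. All percentages are
kept unrounded internally and rounded to two decimals (round-half-even) only
at serialization. An empty junction set produces `null` fields rather than
zeros. Both per-gene variants are provided because published "junctions per
gene" figures are often ambiguous between the two; neither is asserted
against any external value.

### Filtering

Junction confidences live in [0, 1] and attach to junction keys
(chrom, start, end) — every read sharing a junction shares its score, and
lookups are strandless because plain SAM records carry no
strand-of-transcription evidence of their own. A record is dropped iff *any*
junction it spans scores below the threshold (default 0.1): one bad junction
removes a read even if its other junctions are good, matching the
clean-and-remove behaviour of read-level junction filters. Junction-free and
unmapped records are always retained. Filtering operates on text SAM at line
level: header lines and retained records are copied byte-for-byte, so the
output header is identical and no record is mutated; BAM input is not
supported. In strict mode (default) a junction without a score is an error;
lenient mode defaults it to 1.0 and logs.

Three scorers:

- **heuristic** — `w_m·m + w_c·c + w_l·l`, defaults `w = (0.6, 0.2, 0.2)`,
  with `m` = 1.0 (`GT-AG`), 0.6 (`GC-AG`), 0.5 (`AT-AC`), 0.0 (`other`);
  `c = support/(support+5)`; `l = 1` for introns ≤ 100 kb, decaying as
  `exp(-(length-100000)/100000)` beyond; clipped to [0, 1]. This is the
  package's own deterministic junction scorer: transparent, configurable, and
  exactly reproducible — not a learned model. It scores a single combined
  junction confidence (not separate donor/acceptor site scores), and that
  design choice is deliberate and documented rather than asserted equivalent
  to any particular external tool.
- **oracle** — ground-truth lookup on a generator truth table (1.0 true,
  0.0 spurious); exists to make end-to-end equivalence testable.
- **external-table** — a TSV of `chrom, intron_start, intron_end, strand,
  confidence`, so scores from a real splice-site model can be plugged in.
  Duplicate full keys are rejected; the same interval scored on both strands
  keeps the lower confidence (the conservative merge for strandless lookup).

### Expression comparison

CPM is `count / library_size × 10⁶` per sample. A transcript is "expressed"
in a group iff its raw count is positive in ≥ 1 sample of that group;
`ad_only` / `control_only` transcripts (expressed in exactly one group) are
excluded first, then transcripts whose CPM *summed over all samples* is below
0.1 ("total CPM" read literally as a sum; a mean variant would differ only by
the sample-count factor). Multiple testing uses Benjamini–Hochberg — the
standard default of the common DE frameworks — via
`statsmodels.stats.multitest`, checked in the tests against an independent
brute-force step-up. Two significance regimes are supported: stringent
(BH-adjusted p < 0.05) and relaxed (raw p < 0.01), with no fold-change
cut-off in either; direction is the sign of log2FC, and a significant
transcript with exactly zero log2FC stays `ns` with a warning. DE statistics
are consumed as tables — the package does not fit count models.

Arm comparison partitions two transcript sets into shared and exclusive keys,
by exact coordinate tuple (chrom, start, end, strand) by default — the
natural key when two assemblies of the same data must be matched — or by
transcript ID. Duplicate keys within one arm are an error. Fold-change
ranking is by |log2FC| (significant transcripts only), tie-broken by
ascending raw p then transcript ID.

### Literature survey

Gene symbols are deduped case-insensitively (first-seen casing kept, output
sorted), mapped to gene IDs via a two-column TSV (conflicting duplicates
fatal; unmapped symbols reported, never silently dropped and never counted in
denominators). Each mapped gene's document (`<gene_id>.txt` or `.html`) is
searched for the 13 curated keyword stems by case-insensitive substring
containment with no word boundaries — the stems are deliberate truncations,
so one document can match both `neurodegenerat` and `neuro`. Markup tags are
stripped before matching so saved HTML pages behave like their visible text.
Genes without documents are excluded from the denominator and logged, unless
`strict_absent` counts them as processed-but-irrelevant; both conventions are
exposed because published "gene IDs processed" counts do not always state the
choice. The summary percent is `100 × relevant / processed`, round-half-even
to two decimals. The corpus is offline by design: live retrieval of gene
database pages is nondeterministic and version-dependent, so reproducibility
wins; any fetcher that writes `<gene_id>.txt` files can populate a corpus.

## The synthetic-data generator

The generator emulates the *structure* of a two-group brain RNA-seq study:
8 samples per group, negative-binomial counts (var = μ + φμ², φ = 0.1,
per-transcript means uniform on [20, 200] so planted signal clears the CPM
filter), planted DE at log2FC ±2 (75% up, mirroring the up-skew typical of
the disease condition), ~15% spurious junction evidence, and a ~15%
literature-relevant gene fraction. Defaults: 2 chromosomes × 400 kb, 20 genes
× 3 exons of 200 bp, log-normal intron lengths (log-mean 7.0, log-sd 0.6,
floor 60 bp), read length 100, depth 10 reads per true junction.

Artifact classes plant one failure mode each: `noncanonical_motif`
(sub-intron junction with `CC..GG` written into the genome so classification
is guaranteed non-canonical), `ultralong_intron` (> 100 kb, donor in the
first and acceptor in the last gene of a chromosome, spanning multiple loci),
`boundary_shift` (a true junction with one edge displaced 3–30 bp —
syntactically valid, mis-positioned, as aligners emit for partial intron
retention), and `singleton_support` (exactly one supporting read).
`spurious_fraction` is the share of *distinct* junctions in the SAM that are
artifacts (n_spurious = round(f/(1−f) × n_true)); artifact junctions get 2
supporting reads (1 for singletons), deliberately below the ≥ 5-read
threshold so filtering moves every QC metric in the direction it should.
Class counts are allocated by largest remainder, deterministically.

Planted DE p-values are *constructed*, not fitted: nulls uniform on
[0.05, 1), planted DE near 10⁻⁶, so the relaxed regime recovers planted
status exactly and threshold logic is what gets tested. Low-expression plants
are all-zero rows — with realistic library sizes, a total CPM below 0.1 is
only reachable at zero counts — which classify "neither" and are removed by
the CPM filter, not the uniqueness filter. The corpus planter selects
`floor(fraction × n)` relevant genes, embeds 1–3 stems in filler text, and
self-greps every document (bounded regeneration) so non-relevant documents
provably contain no stem.

Each stage draws from its own RNG stream seeded from (seed, stage offset), so
stages are independently reproducible and all outputs are byte-identical for
a fixed seed. Reads are single-end with flag 0 and no quality strings; the
generator makes no attempt at realistic error models, paired-end inserts, or
empirical base quality — so passing tests demonstrate the *logic* of
extraction, filtering and comparison under planted truth, not robustness to
sequencing noise, multimapping ambiguity, or assembler boundary jitter in
real data.

## Problem sizes and numerical choices

The default test and acceptance configurations use ~40–50 distinct junctions
(~400 reads), 200–300 transcripts × 16 samples, and 40–100-gene corpora,
across 5–20 seeds per property — sizes chosen so the full planted-truth
bookkeeping stays exactly checkable while the suite runs in seconds.
Percent rounding is round-half-even via decimal arithmetic (printed-table
proportions reproduce to the digit); BH agreement is asserted to 10⁻¹²; the
heuristic formula to 10⁻⁹. Ties in BH are handled by the step-up itself
(stable); tie-breaks in fold-change ranking are stated above.

## Known limitations

- Text SAM only; no BAM/CRAM, no coordinate-sorting requirement or output.
- Junction scores are per junction key, not per (read, junction) instance;
  an external per-read score list must be collapsed to junction level first.
- Paired-end mate handling is out of scope for the generator; the filter
  removes records independently (a `drop-mates` policy would need mate
  tracking across the stream).
- The literature survey is substring matching, with the false-positive and
  keyword-scope limits that implies; it scores presence, not strength of
  association.
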