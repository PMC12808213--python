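"""Generator correctness: determinism, planted structure, degenerate configs."""

import filecmp

import pandas as pd
import pyfaidx
import pytest

from spliceaudit import synthdata
from spliceaudit.junctions import classify_motif_pair
from spliceaudit.synthdata import SimConfig


def small_config(**overrides) -> SimConfig:
    base = dict(seed=5, n_genes=8, n_chroms=2, chrom_length=300_000,
                n_transcripts=100, depth_per_junction=6)
    base.update(overrides)
    return SimConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"spurious_fraction": 1.5},
            {"de_fraction": 0.7, "unique_fraction": 0.5},
            {"read_length": 10, "min_anchor": 8},
            {"chrom_length": 500},
            {"n_samples_per_group": 1},
            {"spurious_class_weights": {"noncanonical_motif": 0.5}},
            {"spurious_class_weights": {"bogus_class": 1.0}},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    def test_zero_spurious_fraction_ignores_weight_sum(self):
        SimConfig(spurious_fraction=0.0, spurious_class_weights={})


class TestGenome:
    def test_fixed_seed_fasta_byte_identical(self, tmp_path):
        for sub in ("a", "b"):
            synthdata.make_genome(small_config()).write(tmp_path / f"{sub}.fa")
        assert filecmp.cmp(tmp_path / "a.fa", tmp_path / "b.fa", shallow=False)

    def test_record_count_lengths_and_alphabet(self, tmp_path):
        config = small_config(n_chroms=2, chrom_length=50_000, n_genes=4)
        genome = synthdata.make_genome(config)
        genome.write(tmp_path / "g.fa")
        fasta = pyfaidx.Fasta(str(tmp_path / "g.fa"))
        assert len(fasta.keys()) == 2
        for name in fasta.keys():
            seq = str(fasta[name])
            assert len(seq) == 50_000
            assert set(seq) <= set("ACGT")


class TestAnnotation:
    def test_intron_count_and_planted_motifs(self):
        config = small_config(exons_per_gene=3)
        genome = synthdata.make_genome(config)
        annotation = synthdata.make_annotation(genome, config)
        assert len(annotation.genes) == config.n_genes
        strands = set()
        for gene in annotation.genes:
            strands.add(gene.strand)
            assert len(gene.introns) == 2  # k exons -> k-1 introns
            for s, e in gene.introns:
                donor = genome.fetch(gene.chrom, s, s + 2)
                acceptor = genome.fetch(gene.chrom, e - 2, e)
                if gene.strand == "+":
                    assert (donor, acceptor) == ("GT", "AG")
                else:
                    assert (donor, acceptor) == ("CT", "AC")
                assert classify_motif_pair(donor, acceptor) == ("GT-AG", gene.strand)

    def test_infeasible_packing_raises_sizing_error(self):
        config = small_config(chrom_length=12_000, n_genes=40, n_chroms=1)
        genome = synthdata.make_genome(config)
        with pytest.raises(ValueError, match="pack|slot|fit"):
            synthdata.make_annotation(genome, config)


class TestAlignments:
    def test_zero_spurious_fraction_degenerate(self):
        config = small_config(spurious_fraction=0.0)
        genome = synthdata.make_genome(config)
        annotation = synthdata.make_annotation(genome, config)
        _, truth = synthdata.make_alignments(genome, annotation, config)
        assert (truth["label"] == "true").all()
        assert (truth["motif_class"] == "GT-AG").all()

    def test_true_support_forced_by_depth(self):
        config = small_config(
            n_genes=10, exons_per_gene=2, depth_per_junction=20, spurious_fraction=0.0
        )
        genome = synthdata.make_genome(config)
        annotation = synthdata.make_annotation(genome, config)
        _, truth = synthdata.make_alignments(genome, annotation, config)
        assert len(truth) == 10
        assert (truth["support"] == 20).all()

    def test_truth_support_matches_brute_force_sam_walk(
        self, sim_paths, junction_truth, brute_tally
    ):
        tally = brute_tally(sim_paths["sam"])
        truth_map = {
            (r.chrom, r.intron_start, r.intron_end): r.support
            for r in junction_truth.itertuples()
        }
        assert tally == truth_map

    def test_singleton_class_has_support_one(self, junction_truth):
        singles = junction_truth[junction_truth["spurious_class"] == "singleton_support"]
        assert len(singles) >= 1
        assert (singles["support"] == 1).all()

    def test_ultralong_class_exceeds_100kb_across_loci(self, junction_truth):
        ultra = junction_truth[junction_truth["spurious_class"] == "ultralong_intron"]
        assert len(ultra) >= 1
        assert ((ultra["intron_end"] - ultra["intron_start"]) > 100_000).all()

    def test_noncanonical_class_never_canonical(self, junction_truth):
        rows = junction_truth[junction_truth["spurious_class"] == "noncanonical_motif"]
        assert len(rows) >= 1
        assert (rows["motif_class"] == "other").all()


class TestExpression:
    def test_degenerate_fractions_yield_no_planted_entities(self):
        config = small_config(
            unique_fraction=0.0, arm_exclusive_fraction=0.0, de_fraction=0.0,
            low_expression_fraction=0.0,
        )
        expr = synthdata.make_expression(config)
        truth = expr["truth"]
        assert (truth["uniqueness"] == "both").all()
        assert (truth["arm"] == "both_arms").all()
        assert (truth["status"] == "null").all()
        assert len(expr["counts_armA"]) == len(expr["counts_armB"]) == 100

    def test_ad_only_plants_have_zero_control_counts(self, expression_tables):
        truth = expression_tables["truth"]
        counts = expression_tables["counts_armA"].set_index("transcript_id")
        ctrl = expression_tables["control_samples"]
        ad_only = truth.loc[truth["uniqueness"] == "ad_only", "transcript_id"]
        present = [t for t in ad_only if t in counts.index]
        assert present, "fixture should plant ad_only transcripts"
        block = counts.loc[present, ctrl]
        assert (block == 0).all().all()

    def test_exclusive_transcripts_absent_from_other_arm(self, expression_tables):
        truth = expression_tables["truth"]
        a_ids = set(expression_tables["counts_armA"]["transcript_id"])
        b_ids = set(expression_tables["counts_armB"]["transcript_id"])
        for row in truth.itertuples():
            if row.arm == "armA_only":
                assert row.transcript_id in a_ids and row.transcript_id not in b_ids
            elif row.arm == "armB_only":
                assert row.transcript_id in b_ids and row.transcript_id not in a_ids

    def test_planted_pvalues_separated_from_nulls(self, expression_tables):
        truth = expression_tables["truth"].set_index("transcript_id")
        de = expression_tables["de_armA"].set_index("transcript_id")
        merged = de.join(truth["status"])
        assert (merged.loc[merged["status"] != "null", "pvalue"] < 1e-4).all()
        assert (merged.loc[merged["status"] == "null", "pvalue"] >= 0.05).all()


class TestCorpus:
    def test_floor_rounding_and_self_grep(self, tmp_path):
        config = small_config(corpus_relevant_fraction=0.25)
        gene_ids = [f"{1000 + i}" for i in range(100)]
        truth = synthdata.make_corpus(gene_ids, config, outdir=tmp_path)
        assert truth["relevant"].sum() == 25  # floor(0.25 * 100)
        from spliceaudit.litsurvey import DEFAULT_KEYWORDS, match_keywords

        for row in truth.itertuples():
            text = (tmp_path / f"{row.gene_id}.txt").read_text()
            hits = match_keywords(text, DEFAULT_KEYWORDS)
            assert bool(hits) == row.relevant

    @pytest.mark.parametrize("fraction,expected", [(1.0, 100), (0.0, 0)])
    def test_degenerate_fractions(self, fraction, expected):
        config = small_config(corpus_relevant_fraction=fraction)
        truth = synthdata.make_corpus([str(i) for i in range(100)], config)
        assert truth["relevant"].sum() == expected

    def test_empty_keywords_rejected(self):
        with pytest.raises(ValueError):
            synthdata.make_corpus(["1"], small_config(), keywords=[])


class TestSimulateDeterminism:
    def test_fixed_seed_outputs_byte_identical(self, tmp_path):
        config = small_config(n_transcripts=50)
        a = synthdata.simulate(config, tmp_path / "a")
        b = synthdata.simulate(SimConfig(**{**config.__dict__}), tmp_path / "b")
        for key in ("genome", "gtf", "sam", "junction_truth", "counts_armA",
                    "de_armB", "expression_truth", "corpus_truth"):
            assert filecmp.cmp(a[key], b[key], shallow=False), key


class TestConfigFile:
    def test_load_config_roundtrip(self, tmp_path):
        text = (
            "seed = 7\nn_genes = 9\nspurious_fraction = 0.2\n"
            "spurious_class_weights.noncanonical_motif = 1.0\n"
            "# a comment\n\n"
        )
        path = tmp_path / "sim.cfg"
        path.write_text(text)
        config = synthdata.load_config(path)
        assert config.seed == 7
        assert config.n_genes == 9
        assert config.spurious_class_weights == {"noncanonical_motif": 1.0}

    def test_unknown_key_reports_line(self, tmp_path):
        path = tmp_path / "sim.cfg"
        path.write_text("bogus = 1\n")
        with pytest.raises(ValueError, match="unknown config key"):
            synthdata.load_config(path)
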