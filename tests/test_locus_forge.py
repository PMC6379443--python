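import json

import numpy as np
import pytest

from bystander_scan import locus_forge as lf
from bystander_scan.sequtil import revcomp


class TestBuildLocus:
    def test_default_enhancer_length_360(self, default_locus):
        s, e = default_locus.enhancer
        assert e - s == 360

    def test_default_duplication_span_24kb(self):
        dup = lf.DEFAULT_CONFIG["duplication"]
        assert dup["end"] - dup["start"] == 24_000
        assert dup["start"] == lf.DEFAULT_CONFIG["enhancer"][1]

    def test_toy_config_single_exon(self):
        locus = lf.build_locus({"length": 100, "seed": 3, "exons": [[10, 20]]})
        assert len(locus.sequence) == 100
        assert locus.exons == [(10, 20)]

    def test_planted_microhomology_strings_match(self):
        locus = lf.build_locus({
            "length": 200, "seed": 5, "exons": [],
            "microhomology": {"s": 6, "e": 13, "mL": 3, "mR": 0},
        })
        ref = locus.sequence
        assert ref[3:6] == ref[10:13]
        # exact extent: homology does not extend further on either side
        assert ref[2] != ref[9]
        assert ref[13] != ref[6]

    def test_default_microhomology_planted(self, default_locus):
        ref = default_locus.sequence
        s, e = 8_360, 32_360
        assert ref[e - 3:e] == ref[s - 3:s]
        assert ref[e - 4] != ref[s - 4]
        assert ref[e] != ref[s]

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="exon"):
            lf.build_locus({"length": 1000, "seed": 1,
                            "exons": [[10, 50], [40, 80]]})

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config"):
            lf.build_locus({"lenght": 100})

    def test_enhancer_must_be_intronic(self):
        cfg = {"length": 100_000, "seed": 1, "enhancer": [5_050, 5_100]}
        with pytest.raises(ValueError, match="intron"):
            lf.build_locus(cfg)


class TestEdits:
    def test_deletion_simple(self):
        allele = lf.AlleleSequence("AACCGGTT", [], [(0, 8, 0)])
        out = lf.apply_deletion(allele, lf.EditSpec("deletion", 2, 6))
        assert out.sequence == "AATT"

    def test_deletion_identity(self):
        allele = lf.AlleleSequence("AACCGGTT", [], [(0, 8, 0)])
        out = lf.apply_deletion(allele, lf.EditSpec("deletion", 0, 0))
        assert out.sequence == "AACCGGTT"

    def test_enhancer_deletion_removes_360(self, default_locus, edel_allele):
        assert len(default_locus.sequence) - len(edel_allele.sequence) == 360

    def test_duplication_simple(self):
        allele = lf.AlleleSequence("AACCGGTT", [], [(0, 8, 0)])
        out = lf.apply_tandem_duplication(
            allele, lf.EditSpec("tandem_duplication", 2, 6))
        assert out.sequence == "AACCGGCCGGTT"

    def test_duplication_whole_sequence(self):
        allele = lf.AlleleSequence("ACGT", [], [(0, 4, 0)])
        out = lf.apply_tandem_duplication(
            allele, lf.EditSpec("tandem_duplication", 0, 4))
        assert out.sequence == "ACGTACGT"

    def test_idfl_net_length_change(self, default_locus, idfl_allele):
        assert len(idfl_allele) - len(default_locus.sequence) == 24_000 - 360

    def test_duplication_junction_20mer_rule(self, default_locus, idfl_allele):
        ref = default_locus.sequence
        s, e = 8_360, 32_360
        junction_pos = 32_000  # allele coordinate of the novel junction
        observed = idfl_allele.sequence[junction_pos - 10:junction_pos + 10]
        assert observed == ref[e - 10:e] + ref[s:s + 10]

    def test_out_of_range_edit(self, default_locus):
        with pytest.raises(ValueError):
            lf.apply_deletion(default_locus, lf.EditSpec("deletion", 0, 10 ** 6))
        with pytest.raises(ValueError):
            lf.apply_tandem_duplication(
                default_locus, lf.EditSpec("tandem_duplication", 0, 10 ** 6))

    def test_margin_indel(self, default_locus):
        bigger = lf.apply_deletion(
            default_locus,
            lf.EditSpec("deletion", *default_locus.enhancer, margin_indel=4))
        assert len(default_locus.sequence) - len(bigger.sequence) == 364

    def test_liftover_deletion_monotone(self, edel_allele):
        positions = [0, 7_999, 8_000, 50_000, len(edel_allele) - 1]
        mapped = [edel_allele.liftover(p) for p in positions]
        assert mapped == sorted(mapped)
        assert edel_allele.liftover(7_999) == 7_999
        assert edel_allele.liftover(8_000) == 8_360

    def test_liftover_roundtrip_sequence_identity(self, default_locus, idfl_allele):
        # every mapped allele base equals the reference base it lifts to
        ref = default_locus.sequence
        rng = np.random.default_rng(0)
        for p in rng.integers(0, len(idfl_allele), size=500).tolist():
            r = idfl_allele.liftover(p)
            assert r is not None
            assert idfl_allele.sequence[p] == ref[r]


class TestWgsSimulation:
    def test_pair_count_closed_form(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=30_000))
        allele = lf.AlleleSequence(seq, [], [(0, 30_000, 0)])
        rps = lf.simulate_wgs_readpairs(allele, depth=30, read_length=150, seed=4)
        assert len(rps) == 3_000

    def test_error_free_reads_are_substrings(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=5_000))
        allele = lf.AlleleSequence(seq, [], [(0, 5_000, 0)])
        rps = lf.simulate_wgs_readpairs(allele, depth=5, error_rate=0.0, seed=9)
        for pr in rps.pairs[:200]:
            assert pr.read1 in seq
            assert revcomp(pr.read2) in seq

    def test_fragment_length_mean(self, control_wgs):
        from scipy.stats import truncnorm

        _, rps, _ = control_wgs
        lengths = np.array([p.fragment_length for p in rps.pairs])
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        # lower truncation at 2*read_length shifts the mean slightly above 400
        expected = truncnorm.mean((300 - 400) / 60, np.inf, loc=400, scale=60)
        assert abs(lengths.mean() - expected) <= 3 * se

    def test_seed_determinism_fastq(self, tmp_path, default_locus):
        rps_a = lf.simulate_wgs_readpairs(default_locus, depth=2, seed=7)
        rps_b = lf.simulate_wgs_readpairs(default_locus, depth=2, seed=7)
        pa = lf.write_fastq_pair(rps_a, tmp_path / "a")
        pb = lf.write_fastq_pair(rps_b, tmp_path / "b")
        assert pa[0].read_bytes() == pb[0].read_bytes()
        assert pa[1].read_bytes() == pb[1].read_bytes()

    def test_too_short_allele_rejected(self):
        allele = lf.AlleleSequence("ACGT" * 100, [], [(0, 400, 0)])
        with pytest.raises(ValueError, match="shorter"):
            lf.simulate_wgs_readpairs(allele, depth=10)

    def test_depth_conservation(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        allele = lf.AlleleSequence(seq, [], [(0, 20_000, 0)])
        rps = lf.simulate_wgs_readpairs(allele, depth=12, seed=5)
        total = len(rps) * 2 * rps.read_length
        assert abs(total / 20_000 - 12) < 0.01


class TestRnaSimulation:
    def test_printed_default_kmers(self):
        assert lf.E2E2_KMER == "ACCAGCAACTAACTGTGTCT"
        assert lf.E2E3_KMER == "ACCAGCAACTCCCATGACAA"

    def test_pure_proportion(self):
        rna = lf.simulate_rnaseq_reads(None, {"E2E3": 1.0}, 100, seed=3)
        assert len(rna.reads) == 100
        for label, seq in rna.reads:
            assert label == "E2E3"
            assert lf.E2E3_KMER in seq
            assert lf.E2E2_KMER not in seq

    def test_mixture_counts_within_3sd(self):
        n = 11_000
        rna = lf.simulate_rnaseq_reads(
            None, {"E2E3": 10 / 11, "E2E2": 1 / 11}, n, seed=7)
        counts = rna.counts()
        sd = np.sqrt(n * (1 / 11) * (10 / 11))
        assert abs(counts["E2E2"] - 1_000) <= 3 * sd
        assert abs(counts["E2E3"] - 10_000) <= 3 * sd

    def test_empty_label_set_rejected(self):
        with pytest.raises(ValueError):
            lf.simulate_rnaseq_reads(None, {}, 10, seed=0)

    def test_determinism(self):
        a = lf.simulate_rnaseq_reads(None, {"E2E3": 0.5, "E2E2": 0.5}, 50, seed=4)
        b = lf.simulate_rnaseq_reads(None, {"E2E3": 0.5, "E2E2": 0.5}, 50, seed=4)
        assert a.reads == b.reads


class TestCohortVcf:
    samples = ["affected", "s2", "s3"]

    def test_private_variant_serialization(self):
        plan = [lf.PlannedVariant(99, "A", ("G",), "private")]
        table, text = lf.emit_cohort_vcf(plan, self.samples, "affected")
        line = text.strip().splitlines()[-1]
        fields = line.split("\t")
        assert fields[1] == "100"  # 1-based POS
        assert fields[9].startswith("0/1")
        assert fields[10].startswith("0/0")

    def test_roundtrip(self, tmp_path):
        plan = [
            lf.PlannedVariant(99, "A", ("G",), "private"),
            lf.PlannedVariant(200, "C", ("T",), "shared"),
            lf.PlannedVariant(300, "G", ("A", "T"), "multiallelic"),
        ]
        table, text = lf.emit_cohort_vcf(plan, self.samples, "affected")
        path = tmp_path / "cohort.vcf"
        path.write_text(text)
        back = lf.cohort_table_from_vcf(path, "affected")
        assert [(r.pos, r.ref, r.alts, r.genotypes, r.depths)
                for r in back.records] == \
               [(r.pos, r.ref, r.alts, r.genotypes, r.depths)
                for r in table.records]

    def test_multiallelic_alt_field(self):
        plan = [lf.PlannedVariant(10, "G", ("A", "T"), "multiallelic")]
        _, text = lf.emit_cohort_vcf(plan, self.samples, "affected")
        assert "\tA,T\t" in text

    def test_duplicate_positions_rejected(self):
        plan = [lf.PlannedVariant(10, "G", ("A",), "private"),
                lf.PlannedVariant(10, "G", ("T",), "shared")]
        with pytest.raises(ValueError, match="duplicate"):
            lf.emit_cohort_vcf(plan, self.samples, "affected")


def test_truth_json_serializable(default_locus, idfl_allele):
    truth = lf.truth_json(default_locus, [idfl_allele])
    parsed = json.loads(json.dumps(truth))
    assert parsed["duplication"]["span"] == 24_000
    assert parsed["duplication"]["microhomology_left"] == 3
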