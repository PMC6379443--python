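import numpy as np
import pytest

from bystander_scan import align_depth as ad
from bystander_scan import locus_forge as lf
from bystander_scan.sequtil import random_dna, revcomp


@pytest.fixture(scope="module")
def toy_index():
    rng = np.random.default_rng(42)
    seq = random_dna(2_000, rng)
    return ad.ReferenceIndex(seq, "toy")


class TestAlignRead:
    def test_exact_read_maps_at_truth(self, toy_index):
        read = toy_index.sequence[500:650]
        rec = ad.align_read(toy_index, read)
        assert rec.mapped and rec.ref_pos == 500
        assert rec.ops == [("=", 150)]
        assert rec.strand == "+"

    def test_reverse_strand_read(self, toy_index):
        read = revcomp(toy_index.sequence[500:650])
        rec = ad.align_read(toy_index, read)
        assert rec.mapped and rec.ref_pos == 500 and rec.strand == "-"

    def test_all_n_read_unmapped(self, toy_index):
        rec = ad.align_read(toy_index, "N" * 150)
        assert not rec.mapped
        assert rec.cigar() == "*"

    def test_junction_read_soft_clipped(self):
        # tandem duplication of [800, 1400) on a 2-kb toy reference
        rng = np.random.default_rng(7)
        ref = random_dna(2_000, rng)
        allele = ref[:1_400] + ref[800:]
        index = ad.ReferenceIndex(ref, "toy")
        read = allele[1_400 - 75:1_400 + 75]  # 75 bp each side of the junction
        rec = ad.align_read(index, read)
        assert rec.mapped
        clip = max(rec.clipped_left, rec.clipped_right)
        assert clip == 75
        assert rec.aligned_read_bases == 75

    def test_mismatches_encoded(self, toy_index):
        read = list(toy_index.sequence[100:250])
        read[70] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[70]]
        rec = ad.align_read(toy_index, "".join(read))
        assert rec.mapped and rec.ref_pos == 100
        assert rec.ops == [("=", 70), ("X", 1), ("=", 79)]


def _oracle_best_placement(ref: str, read: str):
    """Exhaustive all-positions gapless scored scan (independent oracle)."""
    best_score, best_pos = None, None
    for p in range(len(ref) - len(read) + 1):
        score = sum(1 if ref[p + i] == read[i] else -4 for i in range(len(read)))
        if best_score is None or score > best_score:
            best_score, best_pos = score, p
    return best_pos, best_score


class TestAlignerOracle:
    @pytest.mark.parametrize("case_seed", range(15))
    def test_matches_exhaustive_scan(self, case_seed):
        rng = np.random.default_rng(case_seed)
        ref = random_dna(int(rng.integers(400, 2_000)), rng)
        index = ad.ReferenceIndex(ref, "toy")
        rl = int(rng.integers(40, 61))
        start = int(rng.integers(0, len(ref) - rl))
        read = list(ref[start:start + rl])
        if case_seed % 3 == 0:  # plant one mismatch near the 5' end
            i = int(rng.integers(5, 9))
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        read = "".join(read)
        rec = ad.align_read(index, read)
        oracle_pos, oracle_score = _oracle_best_placement(ref, read)
        assert rec.mapped
        assert rec.score >= oracle_score  # clipping can only help
        if rec.ops[0][0] != "S" and rec.ops[-1][0] != "S":
            assert rec.ref_pos == oracle_pos


class TestPairing:
    def test_proper_pair_flag_and_tlen(self, toy_index):
        frag = toy_index.sequence[300:700]
        r1, r2 = ad.align_read_pair(toy_index, frag[:150], revcomp(frag[-150:]))
        assert r1.proper_pair and r2.proper_pair
        assert r1.tlen == 400 and r2.tlen == -400

    def test_distant_pair_not_proper(self, toy_index):
        r1, r2 = ad.align_read_pair(
            toy_index, toy_index.sequence[0:150],
            revcomp(toy_index.sequence[1_500:1_650]))
        assert not r1.proper_pair


class TestCoverage:
    def test_single_alignment_profile(self):
        rec = ad.AlignmentRecord("r", "A" * 150, ref_pos=100, ops=[("=", 150)],
                                 mapped=True)
        prof = ad.compute_coverage_profile([rec], 3_000, 500)
        np.testing.assert_allclose(prof.depth, [0.3, 0, 0, 0, 0, 0])

    def test_aligned_base_conservation(self):
        recs = [
            ad.AlignmentRecord("a", "A" * 150, ref_pos=0, ops=[("=", 150)],
                               mapped=True),
            ad.AlignmentRecord("b", "A" * 150, ref_pos=1_000, ops=[("=", 150)],
                               mapped=True),
        ]
        prof = ad.compute_coverage_profile(recs, 3_000, 500)
        assert pytest.approx(float((prof.depth * 500).sum())) == 300

    def test_mean_depth_of_30x_simulation(self, control_wgs):
        locus, _, records = control_wgs
        prof = ad.compute_coverage_profile(records, len(locus.sequence), 500)
        mean_depth = float((prof.depth * 500).sum()) / len(locus.sequence)
        assert abs(mean_depth - 30) / 30 < 0.10

    def test_no_alignments_flagged(self):
        prof = ad.compute_coverage_profile([], 1_000, 500)
        assert prof.flagged and prof.normalizer is None
        assert (prof.depth == 0).all()

    def test_control_normalization(self, control_wgs):
        locus, _, records = control_wgs
        prof = ad.compute_coverage_profile(records, len(locus.sequence), 500)
        ratioed = ad.compute_coverage_profile(records, len(locus.sequence), 500,
                                              control=prof)
        assert np.allclose(ratioed.ratio[prof.depth > 0], 1.0)


def _oracle_blocks(ratios, threshold, min_windows):
    """Brute-force elevated-run scan, gap-free (independent of implementation)."""
    blocks, run = [], []
    for i, r in enumerate(list(ratios) + [0.0]):
        if r >= threshold:
            run.append(i)
        else:
            if len(run) >= min_windows:
                blocks.append((run[0], run[-1] + 1))
            run = []
    return blocks


class TestElevatedBlocks:
    def _profile(self, ratios, ws=500):
        ratios = np.asarray(ratios, dtype=float)
        return ad.CoverageProfile(ws, len(ratios) * ws, ratios.copy(),
                                  ratios, 1.0)

    def test_spec_example(self):
        blocks = ad.detect_elevated_blocks(
            self._profile([1, 1, 2, 2, 2, 1]), threshold=1.5,
            min_windows=2, max_gap=0)
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (2 * 500, 5 * 500)
        assert blocks[0].n_windows == 3

    def test_flat_profile_no_blocks(self):
        assert ad.detect_elevated_blocks(self._profile([1.0] * 20)) == []

    def test_gap_tolerance(self):
        ratios = [1, 2, 2, 1, 2, 2, 1, 1]
        blocks = ad.detect_elevated_blocks(
            self._profile(ratios), threshold=1.5, min_windows=4, max_gap=1)
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (1 * 500, 6 * 500)

    @pytest.mark.parametrize("seed", range(10))
    def test_gapfree_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ratios = rng.choice([0.9, 1.0, 1.6, 2.1], size=60)
        blocks = ad.detect_elevated_blocks(
            self._profile(ratios), threshold=1.5, min_windows=3, max_gap=0)
        expected = _oracle_blocks(ratios, 1.5, 3)
        assert [(b.start // 500, b.end // 500) for b in blocks] == expected

    def test_heterozygous_like_signal(self):
        rng = np.random.default_rng(11)
        ratios = np.ones(200)
        ratios[20:68] = rng.normal(1.5, 0.08, size=48)  # binomial-ish noise at 30x
        blocks = ad.detect_elevated_blocks(
            self._profile(ratios), threshold=1.25, min_windows=5, max_gap=1)
        assert len(blocks) == 1
        assert blocks[0].n_windows >= 45

    def test_block_recovers_planted_boundaries(self, idfl_wgs):
        locus, _, records = idfl_wgs
        prof = ad.compute_coverage_profile(records, len(locus.sequence), 500)
        blocks = ad.detect_elevated_blocks(prof)
        assert len(blocks) == 1
        block = blocks[0]
        assert abs(block.start - 8_360) <= 500
        assert abs(block.end - 32_360) <= 500
        # homozygous duplication: block ratio about 2x the flanks
        assert 1.7 < block.mean_ratio < 2.3

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            ad.detect_elevated_blocks(self._profile([1.0]), threshold=0.9)


class TestLibraryStats:
    def _proper(self, tlen):
        return ad.AlignmentRecord("r", "A" * 150, ref_pos=0, ops=[("=", 150)],
                                  mapped=True, proper_pair=True, tlen=tlen)

    def test_median_template(self):
        recs = [self._proper(400), self._proper(400), self._proper(400)]
        median, _ = ad.library_stats(recs, 10_000)
        assert median == 400

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="template"):
            ad.library_stats([], 1_000)

    def test_simulation_library_stats(self, control_wgs):
        locus, _, records = control_wgs
        median, depth = ad.library_stats(records, len(locus.sequence))
        assert abs(median - 400) / 400 < 0.05
        assert abs(depth - 30) / 30 < 0.10


class TestSamIO:
    def test_roundtrip(self, tmp_path, toy_index):
        read = toy_index.sequence[100:250]
        r1, r2 = ad.align_read_pair(
            toy_index, read, revcomp(toy_index.sequence[350:500]))
        path = ad.write_sam([r1, r2], "toy", 2_000, tmp_path / "out.sam")
        back, ref_name, ref_len = ad.read_sam(path)
        assert (ref_name, ref_len) == ("toy", 2_000)
        assert [(r.ref_pos, r.cigar(), r.strand, r.tlen, r.proper_pair)
                for r in back] == \
               [(r.ref_pos, r.cigar(), r.strand, r.tlen, r.proper_pair)
                for r in (r1, r2)]

    def test_ops_sum_to_read_length(self, idfl_wgs):
        _, rps, records = idfl_wgs
        for rec in records[:500]:
            if rec.mapped:
                assert sum(n for op, n in rec.ops if op in "=XIS") == \
                    rps.read_length
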