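"""Minimal seed-and-extend paired-end aligner and coverage segmentation.

Locus-scale only: a k-mer hash index over one contig, gapless scored
extension with soft-clipping (match +1, mismatch -4), FR proper-pair
flagging, windowed depth ratios and elevated-block detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .locus_forge import ReadPairSet
from .sequtil import revcomp

MATCH_SCORE = 1
MISMATCH_SCORE = -4
MIN_ALIGN_SCORE = 25  # below this a placement is reported unmapped
MAX_CANDIDATES = 8


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    """One aligned (or unmapped) read.

    ``ops`` is run-length encoded with CIGAR-style codes: '=' match,
    'X' mismatch, 'I'/'D' indels (unused by the gapless extender), 'S'
    soft-clip. ``seq`` is stored in aligned (reference-forward) orientation.
    """

    query_id: str
    seq: str
    ref_pos: int = -1
    strand: str = "+"
    ops: list[tuple[str, int]] = field(default_factory=list)
    mate_pos: int = -1
    tlen: int = 0
    mapped: bool = False
    proper_pair: bool = False
    score: int = 0
    is_read1: bool = True

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.ops if op in "=XD")

    @property
    def aligned_read_bases(self) -> int:
        return sum(n for op, n in self.ops if op in "=XI")

    @property
    def clipped_left(self) -> int:
        return self.ops[0][1] if self.ops and self.ops[0][0] == "S" else 0

    @property
    def clipped_right(self) -> int:
        return self.ops[-1][1] if self.ops and self.ops[-1][0] == "S" else 0

    @property
    def ref_end(self) -> int:
        return self.ref_pos + self.ref_span

    def cigar(self) -> str:
        if not self.mapped:
            return "*"
        return "".join(f"{n}{op}" for op, n in self.ops)


# ---------------------------------------------------------------------------
# Reference index
# ---------------------------------------------------------------------------

class ReferenceIndex:
    """Exact k-mer position index over a single reference contig."""

    def __init__(self, sequence: str, name: str = "ref", k: int = 21):
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        self.sequence = sequence
        self.name = name
        self.k = k
        self.length = len(sequence)
        self._arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
        index: dict[str, list[int]] = {}
        for i in range(self.length - k + 1):
            index.setdefault(sequence[i:i + k], []).append(i)
        self._index = index

    def seed_hits(self, kmer: str) -> list[int]:
        return self._index.get(kmer, [])


def _best_gapless(ref_arr: np.ndarray, read_arr: np.ndarray,
                  cand: int) -> tuple[int, int, int]:
    """Best local gapless segment of the read placed at candidate offset.

    Returns (score, read_start, read_end) of the maximal-scoring contiguous
    stretch (Kadane via cumulative sums); deterministic first-occurrence ties.
    """
    rl = len(read_arr)
    lo = max(0, -cand)
    hi = min(rl, len(ref_arr) - cand)
    if hi - lo <= 0:
        return (-1, 0, 0)
    mism = ref_arr[cand + lo:cand + hi] != read_arr[lo:hi]
    vals = np.where(mism, MISMATCH_SCORE, MATCH_SCORE)
    cum = np.concatenate(([0], np.cumsum(vals)))
    runmin = np.minimum.accumulate(cum[:-1])
    gains = cum[1:] - runmin
    b = int(np.argmax(gains))
    score = int(gains[b])
    a = int(np.argmin(cum[:b + 1]))
    return (score, lo + a, lo + b + 1)


def _ops_from_segment(ref_arr: np.ndarray, read_arr: np.ndarray, cand: int,
                      a: int, b: int) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    if a > 0:
        ops.append(("S", a))
    mism = ref_arr[cand + a:cand + b] != read_arr[a:b]
    run_op, run_len = None, 0
    for m in mism.tolist():
        op = "X" if m else "="
        if op == run_op:
            run_len += 1
        else:
            if run_op:
                ops.append((run_op, run_len))
            run_op, run_len = op, 1
    if run_op:
        ops.append((run_op, run_len))
    if b < len(read_arr):
        ops.append(("S", len(read_arr) - b))
    return ops


def align_read(index: ReferenceIndex, read: str,
               query_id: str = "read") -> AlignmentRecord:
    """Place one read by seeded gapless extension; both strands tried.

    Ties are broken toward the lowest reference position, then '+' strand.
    Reads with no seed hit (or all-N) come back unmapped.
    """
    best = None  # (score, pos, strand, a, b, oriented, cand)
    best_key: tuple[int, int, bool] | None = None
    rl = len(read)
    k = index.k
    for strand, oriented in (("+", read), ("-", revcomp(read))):
        read_arr = np.frombuffer(oriented.encode(), dtype=np.uint8)
        offsets = {0, max(0, (rl - k) // 2), max(0, rl - k)}
        votes: dict[int, int] = {}
        for off in offsets:
            for p in index.seed_hits(oriented[off:off + k]):
                cand = p - off
                votes[cand] = votes.get(cand, 0) + 1
        if not votes and rl > k:
            # dense fallback: slide the seed across every offset
            for off in range(0, rl - k + 1):
                for p in index.seed_hits(oriented[off:off + k]):
                    cand = p - off
                    votes[cand] = votes.get(cand, 0) + 1
        cands = sorted(votes, key=lambda c: (-votes[c], c))[:MAX_CANDIDATES]
        for cand in cands:
            score, a, b = _best_gapless(index._arr, read_arr, cand)
            pos = cand + a
            key = (score, -pos, strand == "+")
            if best_key is None or key > best_key:
                best, best_key = (score, pos, strand, a, b, oriented, cand), key
    if best is None or best[0] < MIN_ALIGN_SCORE:
        return AlignmentRecord(query_id=query_id, seq=read)
    score, pos, strand, a, b, oriented, cand = best
    read_arr = np.frombuffer(oriented.encode(), dtype=np.uint8)
    ops = _ops_from_segment(index._arr, read_arr, cand, a, b)
    return AlignmentRecord(query_id=query_id, seq=oriented, ref_pos=pos,
                           strand=strand, ops=ops, mapped=True, score=score)


def align_read_pair(index: ReferenceIndex, read1: str, read2: str,
                    fragment_mean: float = 400.0, fragment_sd: float = 60.0,
                    query_id: str = "pair") -> tuple[AlignmentRecord, AlignmentRecord]:
    """Align both mates independently, then set mate/template/proper-pair fields."""
    r1 = align_read(index, read1, query_id)
    r2 = align_read(index, read2, query_id)
    r1.is_read1, r2.is_read1 = True, False
    if r1.mapped and r2.mapped:
        r1.mate_pos, r2.mate_pos = r2.ref_pos, r1.ref_pos
        left, right = (r1, r2) if r1.ref_pos <= r2.ref_pos else (r2, r1)
        tlen = right.ref_end - left.ref_pos
        left.tlen, right.tlen = tlen, -tlen
        proper = (
            left.strand == "+" and right.strand == "-"
            and abs(tlen - fragment_mean) <= 4 * fragment_sd
        )
        r1.proper_pair = r2.proper_pair = proper
    return r1, r2


def align_readpair_set(index: ReferenceIndex,
                       rps: ReadPairSet) -> list[AlignmentRecord]:
    """Align a simulated read-pair set; record ids carry the pair index."""
    records = []
    for i, pr in enumerate(rps.pairs):
        r1, r2 = align_read_pair(index, pr.read1, pr.read2,
                                 rps.fragment_mean, rps.fragment_sd,
                                 query_id=f"pair{i}")
        records.extend((r1, r2))
    return records


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageProfile:
    window_size: int
    ref_length: int
    depth: np.ndarray  # aligned bases per window / window_size
    ratio: np.ndarray
    normalizer: float | None
    flagged: bool = False

    @property
    def n_windows(self) -> int:
        return len(self.depth)

    def windows(self) -> list[tuple[int, int]]:
        return [(i * self.window_size,
                 min((i + 1) * self.window_size, self.ref_length))
                for i in range(self.n_windows)]


def compute_coverage_profile(alignments: Iterable[AlignmentRecord],
                             ref_length: int, window_size: int = 500,
                             control: "CoverageProfile | None" = None) -> CoverageProfile:
    """Windowed aligned-base depth, normalized by the sample's median window
    depth (default) or per-window by a control profile."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    base = np.zeros(ref_length, dtype=np.int32)
    total = 0
    for rec in alignments:
        if not rec.mapped:
            continue
        s, e = rec.ref_pos, min(rec.ref_end, ref_length)
        if e > s:
            base[s:e] += 1
            total += e - s
    n_win = (ref_length + window_size - 1) // window_size
    edges = np.arange(0, n_win * window_size, window_size)
    sums = np.add.reduceat(base, edges)
    depth = sums / window_size
    if total == 0:
        return CoverageProfile(window_size, ref_length, depth,
                               np.zeros(n_win), None, flagged=True)
    if control is not None:
        if control.n_windows != n_win or control.window_size != window_size:
            raise ValueError("control profile window grid mismatch")
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(control.depth > 0, depth / control.depth, 0.0)
        return CoverageProfile(window_size, ref_length, depth, ratio, None)
    normalizer = float(np.median(depth))
    ratio = depth / normalizer if normalizer > 0 else np.zeros(n_win)
    return CoverageProfile(window_size, ref_length, depth, ratio, normalizer)


@dataclass(frozen=True)
class ElevatedBlock:
    start: int  # bp, window-aligned
    end: int
    mean_ratio: float
    n_windows: int


def detect_elevated_blocks(profile: CoverageProfile, threshold: float = 1.4,
                           min_windows: int = 5, max_gap: int = 1) -> list[ElevatedBlock]:
    """Maximal runs of windows with ratio >= threshold, tolerating gaps of up
    to ``max_gap`` consecutive sub-threshold windows inside a run."""
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    ratio = profile.ratio
    ws = profile.window_size
    blocks: list[ElevatedBlock] = []
    i, n = 0, len(ratio)
    while i < n:
        if ratio[i] < threshold:
            i += 1
            continue
        j, gap, last_hot = i, 0, i
        while j < n:
            if ratio[j] >= threshold:
                gap, last_hot = 0, j
                j += 1
            elif gap < max_gap:
                gap += 1
                j += 1
            else:
                break
        span = last_hot - i + 1
        if span >= min_windows:
            start = i * ws
            end = min((last_hot + 1) * ws, profile.ref_length)
            blocks.append(ElevatedBlock(
                start=start, end=end,
                mean_ratio=float(np.mean(ratio[i:last_hot + 1])),
                n_windows=span))
        i = last_hot + 1
    return blocks


def library_stats(alignments: Sequence[AlignmentRecord],
                  ref_length: int) -> tuple[float, float]:
    """(median |template length| over proper pairs, mean aligned depth)."""
    templates = [rec.tlen for rec in alignments
                 if rec.mapped and rec.proper_pair and rec.tlen > 0]
    if not templates:
        raise ValueError("median template length undefined: no proper pairs")
    total_aligned = sum(rec.aligned_read_bases - _insertions(rec)
                        for rec in alignments if rec.mapped)
    return float(np.median(templates)), total_aligned / ref_length


def _insertions(rec: AlignmentRecord) -> int:
    return sum(n for op, n in rec.ops if op == "I")


# ---------------------------------------------------------------------------
# SAM I/O
# ---------------------------------------------------------------------------

_FLAG_PAIRED = 0x1
_FLAG_PROPER = 0x2
_FLAG_UNMAPPED = 0x4
_FLAG_REVERSE = 0x10
_FLAG_MATE_REVERSE = 0x20
_FLAG_READ1 = 0x40
_FLAG_READ2 = 0x80


def write_sam(records: Sequence[AlignmentRecord], ref_name: str,
              ref_length: int, path: str | Path) -> Path:
    """Minimal single-contig SAM text writer (1-based POS at the boundary)."""
    path = Path(path)
    by_id: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_id.setdefault(rec.query_id, []).append(rec)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{ref_name}\tLN:{ref_length}\n")
        fh.write("@PG\tID:bystander-scan\tPN:bystander-scan\n")
        for rec in records:
            mates = by_id[rec.query_id]
            mate = next((m for m in mates if m is not rec), None)
            flag = _FLAG_PAIRED
            flag |= _FLAG_READ1 if rec.is_read1 else _FLAG_READ2
            if not rec.mapped:
                flag |= _FLAG_UNMAPPED
            if rec.strand == "-":
                flag |= _FLAG_REVERSE
            if rec.proper_pair:
                flag |= _FLAG_PROPER
            if mate is not None and mate.mapped and mate.strand == "-":
                flag |= _FLAG_MATE_REVERSE
            pos = rec.ref_pos + 1 if rec.mapped else 0
            pnext = rec.mate_pos + 1 if rec.mate_pos >= 0 else 0
            fh.write("\t".join([
                rec.query_id, str(flag), ref_name if rec.mapped else "*",
                str(pos), "60" if rec.mapped else "0", rec.cigar(),
                "=" if pnext else "*", str(pnext), str(rec.tlen),
                rec.seq, "*",
            ]) + "\n")
    return path


def read_sam(path: str | Path) -> tuple[list[AlignmentRecord], str, int]:
    """Load alignments from SAM text (external aligner output accepted)."""
    import pysam

    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        ref_name = sam.references[0] if sam.nreferences else "ref"
        ref_length = sam.lengths[0] if sam.nreferences else 0
        for aln in sam:
            ops: list[tuple[str, int]] = []
            if aln.cigartuples:
                code = {0: "=", 1: "I", 2: "D", 3: "D", 4: "S", 7: "=", 8: "X"}
                for op, n in aln.cigartuples:
                    if op in code:
                        ops.append((code[op], n))
            records.append(AlignmentRecord(
                query_id=aln.query_name or "read",
                seq=aln.query_sequence or "",
                ref_pos=aln.reference_start if not aln.is_unmapped else -1,
                strand="-" if aln.is_reverse else "+",
                ops=ops,
                mate_pos=aln.next_reference_start
                if aln.next_reference_start is not None else -1,
                tlen=aln.template_length,
                mapped=not aln.is_unmapped,
                proper_pair=aln.is_proper_pair,
                is_read1=not aln.is_read2,
            ))
    return records, ref_name, ref_length


def write_coverage_tsv(profile: CoverageProfile, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("start\tend\tdepth\tratio\n")
        for (s, e), d, r in zip(profile.windows(), profile.depth, profile.ratio):
            fh.write(f"{s}\t{e}\t{d:.4f}\t{r:.4f}\n")
    return path
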