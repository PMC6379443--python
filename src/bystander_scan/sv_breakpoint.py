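"""Breakpoint characterization: discordant-pair classification, de Bruijn
junction assembly, base-pair breakpoint placement, and homology scans.

The junction contig is assembled from soft-clipped reads plus mates of
everted (outward-facing) pairs, then its flanks are placed on the reference
to derive (e, s): the junction uses reference sequence ending at ``e`` and
resumes at ``s``. For a tandem duplication s < e. The reported breakpoint is
the left-aligned representative within the microhomology ambiguity range.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .align_depth import AlignmentRecord
from .sequtil import revcomp

PAIR_LABELS = ("proper", "everted_dup", "long_insert_del",
               "same_strand_inv", "interchrom", "unpaired")


class JunctionError(Exception):
    """Base class for junction-assembly failures."""


class NoJunctionError(JunctionError):
    """Too little evidence: no junction callable."""


class AmbiguousJunctionError(JunctionError):
    """Branching assembly graph or non-unique flank placement."""


# ---------------------------------------------------------------------------
# Pair classification
# ---------------------------------------------------------------------------

def classify_read_pair(r1: AlignmentRecord, r2: AlignmentRecord,
                       fragment_mean: float = 400.0,
                       fragment_sd: float = 60.0) -> str:
    """Assign one of the PAIR_LABELS to a mate pair.

    FR pairs with |template| within mean +/- 4 sd are proper; outward-facing
    (leftmost mate reverse, rightmost forward) pairs are the tandem-duplication
    signature; over-long FR templates suggest a deletion; same-strand mates an
    inversion. Short FR templates are kept as proper (insertion calling is out
    of scope here).
    """
    if not (r1.mapped and r2.mapped):
        return "unpaired"
    if r1.strand == r2.strand:
        return "same_strand_inv"
    left, right = (r1, r2) if r1.ref_pos <= r2.ref_pos else (r2, r1)
    tlen = abs(left.tlen) if left.tlen else right.ref_end - left.ref_pos
    if left.strand == "-" and right.strand == "+":
        return "everted_dup"
    if tlen > fragment_mean + 4 * fragment_sd:
        return "long_insert_del"
    return "proper"


def classify_pairs(records: Sequence[AlignmentRecord],
                   fragment_mean: float = 400.0,
                   fragment_sd: float = 60.0) -> dict[str, int]:
    """Label counts over all mate pairs in a record stream."""
    counts = {label: 0 for label in PAIR_LABELS}
    for r1, r2 in _iter_pairs(records):
        counts[classify_read_pair(r1, r2, fragment_mean, fragment_sd)] += 1
    return counts


def _iter_pairs(records: Sequence[AlignmentRecord]):
    by_id: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_id.setdefault(rec.query_id, []).append(rec)
    for recs in by_id.values():
        if len(recs) == 2:
            yield recs[0], recs[1]


def recruit_candidate_reads(records: Sequence[AlignmentRecord],
                            fragment_mean: float = 400.0,
                            fragment_sd: float = 60.0,
                            min_clip: int = 20) -> list[str]:
    """Reads feeding junction assembly: soft-clipped alignments (>= min_clip)
    plus both mates of everted pairs, in reference-forward orientation."""
    out: list[str] = []
    seen: set[int] = set()
    for rec in records:
        if rec.mapped and (rec.clipped_left >= min_clip
                           or rec.clipped_right >= min_clip):
            out.append(rec.seq)
            seen.add(id(rec))
    for r1, r2 in _iter_pairs(records):
        if classify_read_pair(r1, r2, fragment_mean, fragment_sd) == "everted_dup":
            for rec in (r1, r2):
                if id(rec) not in seen:
                    out.append(rec.seq)
                    seen.add(id(rec))
    return out


# ---------------------------------------------------------------------------
# Junction assembly
# ---------------------------------------------------------------------------

@dataclass
class BreakpointJunction:
    contig: str
    left_break: int   # e: junction uses reference ending here (exclusive)
    right_break: int  # s: junction resumes here
    orientation: str  # tandem_duplication | deletion | inversion
    microhomology_left: int
    microhomology_right: int
    inserted_sequence: str
    support: int

    @property
    def microhomology_total(self) -> int:
        return self.microhomology_left + self.microhomology_right


def assemble_junction(candidate_reads: Sequence[str], reference: str,
                      k: int = 31, min_support: int = 3) -> BreakpointJunction:
    """Assemble the breakpoint-spanning contig and place it on the reference.

    Builds a de Bruijn graph from candidate reads (dropping singleton k-mers
    when evidence is plentiful), extracts the maximal unambiguous path through
    a reference-novel k-mer, and aligns the contig flanks to the reference.
    Raises :class:`NoJunctionError` / :class:`AmbiguousJunctionError`.
    """
    reads = [r for r in candidate_reads if r]
    if len(reads) < min_support:
        raise NoJunctionError(f"no junction: {len(reads)} candidate reads "
                              f"(min_support={min_support})")
    min_read = min(len(r) for r in reads)
    if k >= min_read:
        k = min_read - 2 if (min_read - 2) % 2 == 1 else min_read - 3
    if k % 2 == 0:
        k += 1
    if k < 11:
        raise NoJunctionError("reads too short for assembly")

    counts: Counter[str] = Counter()
    for read in reads:
        for i in range(len(read) - k + 1):
            km = read[i:i + k]
            if "N" not in km:
                counts[km] += 1
    if len(reads) >= 10:
        counts = Counter({km: c for km, c in counts.items() if c > 1})

    ref_kmers = {reference[i:i + k] for i in range(len(reference) - k + 1)}
    novel = [km for km in counts if km not in ref_kmers]
    if not novel:
        raise NoJunctionError("no junction: no reference-novel k-mers")
    seed = max(novel, key=lambda km: (counts[km], km))
    contig = _unitig(seed, counts)

    junction = _place_flanks(contig, reference, k)
    e, s, inserted = junction
    orientation = "tandem_duplication" if s < e else "deletion"
    mh_l, mh_r = scan_microhomology(reference, e, s, orientation) \
        if not inserted else (0, 0)
    contig_novel = {contig[i:i + k] for i in range(len(contig) - k + 1)} - ref_kmers
    support = sum(1 for r in reads
                  if any(r[i:i + k] in contig_novel for i in range(len(r) - k + 1)))
    if support < min_support:
        raise NoJunctionError(f"no junction: support {support} < {min_support}")
    return BreakpointJunction(
        contig=contig, left_break=e, right_break=s, orientation=orientation,
        microhomology_left=mh_l, microhomology_right=mh_r,
        inserted_sequence=inserted, support=support)


def _unitig(seed: str, counts: Counter) -> str:
    """Maximal unambiguous de Bruijn path through the seed k-mer."""
    def extend(start: str, forward: bool) -> str:
        cur, grown, visited = start, "", {start}
        while True:
            if forward:
                nxt = [cur[1:] + b for b in "ACGT" if cur[1:] + b in counts]
                back = lambda n: [a + n[:-1] for a in "ACGT" if a + n[:-1] in counts]
            else:
                nxt = [b + cur[:-1] for b in "ACGT" if b + cur[:-1] in counts]
                back = lambda n: [n[1:] + a for a in "ACGT" if n[1:] + a in counts]
            if len(nxt) != 1 or len(back(nxt[0])) != 1 or nxt[0] in visited:
                return grown
            cur = nxt[0]
            visited.add(cur)
            grown = grown + cur[-1] if forward else cur[0] + grown
    return extend(seed, False) + seed + extend(seed, True)


def _place_flanks(contig: str, reference: str, k: int,
                  min_flank: int = 25) -> tuple[int, int, str]:
    """Place contig prefix and suffix on the reference; return (e, s, inserted)
    with the left-aligned junction representative."""
    C = len(contig)
    p1, A = _longest_prefix_placement(contig, reference)
    p2, B = _longest_suffix_placement(contig, reference)
    if A < min_flank or B < min_flank:
        raise AmbiguousJunctionError("ambiguous: contig flank not placeable")
    overlap = A + B - C
    if overlap >= 0:
        j = C - B  # left-aligned junction offset in the contig
        e = p1 + j
        s = p2
        inserted = ""
    else:
        e = p1 + A
        s = p2
        inserted = contig[A:C - B]
    if e == s:
        raise AmbiguousJunctionError("ambiguous: degenerate breakpoints")
    return e, s, inserted


def _longest_prefix_placement(contig: str, reference: str) -> tuple[int, int]:
    probe = contig[:25]
    hits = _find_all(reference, probe)
    if not hits:
        raise AmbiguousJunctionError("ambiguous: contig prefix absent from reference")
    best_pos, best_len, ties = -1, -1, 0
    for p in hits:
        n = _match_len(reference, p, contig)
        if n > best_len:
            best_pos, best_len, ties = p, n, 1
        elif n == best_len:
            ties += 1
    if ties > 1:
        raise AmbiguousJunctionError("ambiguous: multiple prefix placements")
    return best_pos, best_len


def _longest_suffix_placement(contig: str, reference: str) -> tuple[int, int]:
    probe = contig[-25:]
    hits = _find_all(reference, probe)
    if not hits:
        raise AmbiguousJunctionError("ambiguous: contig suffix absent from reference")
    best_pos, best_len, ties = -1, -1, 0
    for p in hits:
        # p is where the last 25 bases sit; extend the match backwards
        n = _match_len_back(reference, p + len(probe), contig)
        if n > best_len:
            best_pos, best_len, ties = p + len(probe) - n, n, 1
        elif n == best_len:
            ties += 1
    if ties > 1:
        raise AmbiguousJunctionError("ambiguous: multiple suffix placements")
    return best_pos, best_len


def _find_all(text: str, pattern: str) -> list[int]:
    out, start = [], 0
    while True:
        i = text.find(pattern, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def _match_len(reference: str, p: int, contig: str) -> int:
    n = 0
    while n < len(contig) and p + n < len(reference) and reference[p + n] == contig[n]:
        n += 1
    return n


def _match_len_back(reference: str, ref_end: int, contig: str) -> int:
    n = 0
    while n < len(contig) and ref_end - n - 1 >= 0 and \
            reference[ref_end - n - 1] == contig[len(contig) - n - 1]:
        n += 1
    return n


# ---------------------------------------------------------------------------
# Homology scans
# ---------------------------------------------------------------------------

def scan_microhomology(reference: str, e: int, s: int,
                       orientation: str = "tandem_duplication") -> tuple[int, int]:
    """Microhomology at a junction joining ...ref[:e] to ref[s:]...

    left  = max m with ref[e-m:e] == ref[s-m:s]
    right = max m with ref[e:e+m] == ref[s:s+m]
    The total left+right is the breakpoint ambiguity range.
    """
    L = len(reference)
    if not (0 <= s <= L and 0 <= e <= L):
        raise ValueError("breakpoints out of range")
    if s == e:
        raise ValueError("degenerate junction: s == e")
    left = 0
    while e - left - 1 >= 0 and s - left - 1 >= 0 and \
            reference[e - left - 1] == reference[s - left - 1]:
        left += 1
    right = 0
    while e + right < L and s + right < L and \
            reference[e + right] == reference[s + right]:
        right += 1
    return left, right


@dataclass(frozen=True)
class SharedSegment:
    """A maximal exact match between the cut-site window and a junction window."""
    cut_pos: int       # reference coordinate within the cut-site window
    junction_pos: int  # reference coordinate within the junction window
    length: int
    strand: str        # '+' or '-': orientation of the junction-window copy
    anchor: str        # 'e' or 's'


def scan_extended_homology(reference: str, cut_site: int, e: int, s: int,
                           window: int = 200, min_len: int = 10) -> list[SharedSegment]:
    """All maximal exact matches >= min_len between the sequence around the cut
    site and the sequence around each breakpoint, on both strands. An empty
    list means no extended homology. When the two windows overlap on the
    reference, forward matches of a position with itself are excluded."""
    L = len(reference)
    a_lo, a_hi = max(0, cut_site - window), min(L, cut_site + window)
    if (a_lo, a_hi) != (cut_site - window, cut_site + window):
        warnings.warn("cut-site window truncated to sequence bounds")
    win_a = reference[a_lo:a_hi]
    out: list[SharedSegment] = []
    for anchor, pos in (("e", e), ("s", s)):
        b_lo, b_hi = max(0, pos - window), min(L, pos + window)
        if (b_lo, b_hi) != (pos - window, pos + window):
            warnings.warn("junction window truncated to sequence bounds")
        win_b = reference[b_lo:b_hi]
        for strand, text_b in (("+", win_b), ("-", revcomp(win_b))):
            for i, j, n in _maximal_matches(win_a, text_b, min_len):
                jb = b_lo + (j if strand == "+" else len(win_b) - j - n)
                if strand == "+" and a_lo + i == jb:
                    continue  # same reference bases seen through both windows
                out.append(SharedSegment(cut_pos=a_lo + i, junction_pos=jb,
                                         length=n, strand=strand, anchor=anchor))
    return sorted(out, key=lambda m: (m.anchor, m.strand, m.cut_pos, m.junction_pos))


def _maximal_matches(a: str, b: str, min_len: int) -> list[tuple[int, int, int]]:
    """Maximal exact matches between two short strings via diagonal run scan."""
    out = []
    la, lb = len(a), len(b)
    for d in range(-lb + 1, la):  # diagonal: i - j = d
        i = max(0, d)
        j = i - d
        run = 0
        while i <= la and j <= lb:
            if i < la and j < lb and a[i] == b[j]:
                run += 1
            else:
                if run >= min_len:
                    out.append((i - run, j - run, run))
                run = 0
            i += 1
            j += 1
    return out
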