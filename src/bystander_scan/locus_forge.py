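"""Synthetic edited-locus generator.

Builds truth-annotated locus models, edited haplotypes (enhancer deletion,
tandem duplication with planted breakpoint microhomology), paired-end WGS
read sets, junction-spanning RNA read mixtures, and small cohort VCFs.
All randomness is seeded; identical config + seed gives identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequtil import BASES, is_dna, random_dna, revcomp

# Splice-junction signature strings planted at exon boundaries of the default
# locus so that the E2-E2 / E2-E3 junction 20-mers are fixed, known strings.
E2_START = "AACTGTGTCT"
E2_END = "ACCAGCAACT"
E3_START = "CCCATGACAA"
E2E2_KMER = E2_END + E2_START  # aberrant exon2-exon2 junction 20-mer
E2E3_KMER = E2_END + E3_START  # wild-type exon2-exon3 junction 20-mer

STOP_CODONS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LocusModel:
    """Reference locus with annotated features (0-based half-open intervals)."""

    name: str
    sequence: str
    enhancer: tuple[int, int] | None
    exons: list[tuple[int, int]]  # ordered, disjoint; exon i+1 numbered i+1
    cds_start: int | None
    strand: str = "+"
    primer_sites: dict[str, tuple[int, int]] = field(default_factory=dict)
    cut_sites: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_locus(self)

    def __len__(self) -> int:
        return len(self.sequence)

    def exon_sequence(self, number: int) -> str:
        s, e = self.exons[number - 1]
        return self.sequence[s:e]

    def transcript_positions(self) -> np.ndarray:
        """Genomic position of every transcript base (exons concatenated)."""
        return np.concatenate(
            [np.arange(s, e) for s, e in self.exons]
        )

    def transcript(self) -> str:
        return "".join(self.sequence[s:e] for s, e in self.exons)

    def primer_sequence(self, name: str, orientation: str = "+") -> str:
        s, e = self.primer_sites[name]
        seq = self.sequence[s:e]
        return seq if orientation == "+" else revcomp(seq)


def validate_locus(locus: LocusModel) -> None:
    L = len(locus.sequence)
    if not is_dna(locus.sequence):
        raise ValueError("locus sequence must be non-empty over {A,C,G,T}")
    if locus.strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    prev_end = -1
    for i, (s, e) in enumerate(locus.exons, start=1):
        if not (0 <= s < e <= L):
            raise ValueError(f"exon {i} [{s},{e}) out of range for length {L}")
        if s <= prev_end:
            raise ValueError(f"exon {i} overlaps or is out of order")
        prev_end = e
    if locus.enhancer is not None:
        es, ee = locus.enhancer
        if not (0 <= es < ee <= L):
            raise ValueError(f"enhancer [{es},{ee}) out of range")
        if len(locus.exons) >= 2:
            intronic = any(
                a_end <= es and ee <= b_start
                for (_, a_end), (b_start, _) in zip(locus.exons, locus.exons[1:])
            )
            if not intronic:
                raise ValueError("enhancer must lie within an intron")
    for name, (s, e) in locus.primer_sites.items():
        if not (0 <= s < e <= L):
            raise ValueError(f"primer site {name} [{s},{e}) out of range")
    for name, pos in locus.cut_sites.items():
        if not (0 <= pos <= L):
            raise ValueError(f"cut site {name} at {pos} out of range")
    if locus.cds_start is not None and \
            not any(s <= locus.cds_start < e for s, e in locus.exons):
        raise ValueError("cds_start must fall inside an exon")


@dataclass(frozen=True)
class EditSpec:
    """A single haplotype edit in the coordinates of the sequence it is applied to."""

    kind: str  # "deletion" | "tandem_duplication"
    start: int
    end: int
    margin_indel: int = 0  # deletions only: signed adjustment of the deleted span
    planted_microhomology: tuple[int, int] = (0, 0)  # duplications: (left, right) bp

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "tandem_duplication"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if not 0 <= self.start <= self.end:
            raise ValueError("edit requires 0 <= start <= end")
        if self.margin_indel and self.kind != "deletion":
            raise ValueError("margin_indel applies only to deletions")


@dataclass
class AlleleSequence:
    """An edited haplotype plus a piecewise liftover map to the reference.

    ``segments`` is a list of (allele_start, allele_end, ref_start) blocks:
    allele positions in [allele_start, allele_end) map to
    ref_start + (pos - allele_start).
    """

    sequence: str
    edits: list[EditSpec]
    segments: list[tuple[int, int, int]]
    allele_id: str = "allele"

    def __len__(self) -> int:
        return len(self.sequence)

    def liftover(self, pos: int) -> int | None:
        """Reference coordinate of allele position ``pos`` (None if unmapped)."""
        for a_start, a_end, r_start in self.segments:
            if a_start <= pos < a_end:
                return r_start + (pos - a_start)
        return None


def _as_allele(obj: "LocusModel | AlleleSequence", allele_id: str) -> AlleleSequence:
    if isinstance(obj, AlleleSequence):
        return obj
    return AlleleSequence(
        sequence=obj.sequence,
        edits=[],
        segments=[(0, len(obj.sequence), 0)],
        allele_id=allele_id,
    )


def _compose(new_map: list[tuple[int, int, int]],
             inner: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Compose a (new -> input) piecewise map with an (input -> ref) map."""
    out: list[tuple[int, int, int]] = []
    for n_start, n_end, i_start in new_map:
        need = n_end - n_start
        offset = 0
        for a_start, a_end, r_start in inner:
            lo = max(a_start, i_start + offset)
            hi = min(a_end, i_start + need)
            if lo < hi and lo == i_start + offset:
                out.append((n_start + offset, n_start + offset + (hi - lo),
                            r_start + (lo - a_start)))
                offset += hi - lo
            if offset == need:
                break
        if offset != need:
            raise ValueError("liftover composition gap")
    # merge adjacent collinear blocks
    merged: list[tuple[int, int, int]] = []
    for seg in out:
        if merged and merged[-1][1] == seg[0] and \
                merged[-1][2] + (merged[-1][1] - merged[-1][0]) == seg[2]:
            merged[-1] = (merged[-1][0], seg[1], merged[-1][2])
        else:
            merged.append(seg)
    return merged


# ---------------------------------------------------------------------------
# Locus construction
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "name": "synthetic_locus",
    "length": 100_000,
    "seed": 1234,
    "exons": [
        [5_000, 5_200], [12_000, 12_181], [35_000, 35_150], [40_000, 40_120],
        [48_000, 48_140], [56_000, 56_130], [64_000, 64_160], [72_000, 73_200],
    ],
    "enhancer": [8_000, 8_360],
    "cds_start": 5_030,
    "strand": "+",
    "cut_sites": {"gRNA_L": 8_000, "gRNA_R": 8_360},
    "primer_sites": {
        "EDEL_F": [7_700, 7_720], "EDEL_R": [8_600, 8_620],
        "DUPJ_F": [32_200, 32_220], "DUPJ_R": [8_450, 8_470],
    },
    # 24-kb duplication starting immediately downstream of the enhancer,
    # with 3 nt of planted breakpoint microhomology on the left.
    "duplication": {"start": 8_360, "end": 32_360},
    "microhomology": {"s": 8_360, "e": 32_360, "mL": 3, "mR": 0},
    "plant_splice_kmers": True,
    "plant_orf": True,
}

_CONFIG_KEYS = set(DEFAULT_CONFIG)


def default_config() -> dict:
    return json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy


def build_locus(config: Mapping | None = None) -> LocusModel:
    """Construct a :class:`LocusModel` from a configuration mapping.

    Unspecified keys fall back to the packaged default ("IDFL-like") config:
    a 100-kb locus, an 8-exon gene, a 360-bp intronic enhancer, a 24,000-bp
    duplication span starting immediately downstream of the enhancer, and
    3 nt of planted left microhomology at the duplication breakpoints.
    """
    cfg = default_config()
    if config is not None:
        unknown = set(config) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update({k: v for k, v in config.items() if v is not None})
        if config.get("exons") is not None and "cds_start" not in config:
            cfg["plant_orf"] = False
    L = int(cfg["length"])
    rng = np.random.default_rng(int(cfg["seed"]))
    seq = list(random_dna(L, rng))

    if config is not None and config.get("exons") is not None:
        exons = [tuple(map(int, iv)) for iv in config["exons"]]
    else:
        exons = [tuple(map(int, iv)) for iv in cfg["exons"] if iv[1] <= L]
    protected: set[int] = set()

    if cfg["plant_splice_kmers"] and len(exons) >= 3:
        _plant(seq, exons[1][0], E2_START, protected)
        _plant(seq, exons[1][1] - len(E2_END), E2_END, protected)
        _plant(seq, exons[2][0], E3_START, protected)

    mh = cfg.get("microhomology")
    if mh and mh["e"] <= L:
        _plant_microhomology(seq, int(mh["s"]), int(mh["e"]),
                             int(mh["mL"]), int(mh["mR"]), protected)
    elif mh and mh["e"] > L:
        mh = None

    cds_start: int | None = int(cfg["cds_start"])
    if not any(s <= cds_start < e for s, e in exons):
        cds_start = None
    if cfg["plant_orf"] and cds_start is not None:
        _plant_orf(seq, exons, cds_start, protected)

    enhancer = tuple(map(int, cfg["enhancer"])) if cfg["enhancer"] else None
    if enhancer is not None and enhancer[1] > L:
        enhancer = None

    locus = LocusModel(
        name=str(cfg["name"]),
        sequence="".join(seq),
        enhancer=enhancer,
        exons=exons,
        cds_start=cds_start,
        strand=str(cfg["strand"]),
        primer_sites={k: tuple(map(int, v)) for k, v in cfg["primer_sites"].items()
                      if v[1] <= L},
        cut_sites={k: int(v) for k, v in cfg["cut_sites"].items() if v <= L},
    )
    if mh:
        _check_junction_unique(locus.sequence, int(mh["s"]), int(mh["e"]))
    return locus


def _plant(seq: list[str], pos: int, text: str, protected: set[int]) -> None:
    if pos < 0 or pos + len(text) > len(seq):
        raise ValueError(f"planted string at {pos} out of range")
    for i, b in enumerate(text):
        seq[pos + i] = b
        protected.add(pos + i)


def _plant_microhomology(seq: list[str], s: int, e: int, mL: int, mR: int,
                         protected: set[int]) -> None:
    """Copy s-side sequence onto the e-side so that the maximal microhomology
    at the (e, s) junction is exactly (mL, mR)."""
    if not (0 <= s - mL and e + mR <= len(seq) and s < e):
        raise ValueError("microhomology plant out of range")
    for i in range(mL):
        seq[e - mL + i] = seq[s - mL + i]
        protected.update({e - mL + i, s - mL + i})
    for i in range(mR):
        seq[e + i] = seq[s + i]
        protected.update({e + i, s + i})
    # cap the homology so it does not extend beyond the requested lengths
    if e - mL - 1 >= 0 and s - mL - 1 >= 0 and seq[e - mL - 1] == seq[s - mL - 1]:
        seq[e - mL - 1] = _different_base(seq[s - mL - 1])
        protected.add(e - mL - 1)
    if e + mR < len(seq) and s + mR < len(seq) and seq[e + mR] == seq[s + mR]:
        seq[e + mR] = _different_base(seq[s + mR])
        protected.add(e + mR)


def _different_base(b: str) -> str:
    return BASES[(BASES.index(b) + 1) % 4]


def _check_junction_unique(ref: str, s: int, e: int) -> None:
    j20 = ref[e - 10:e] + ref[s:s + 10]
    if j20 in ref:
        raise ValueError(
            "planted junction 20-mer occurs in the reference; change the seed")


def _plant_orf(seq: list[str], exons: Sequence[tuple[int, int]],
               cds_start: int, protected: set[int]) -> None:
    """Make the single-copy-per-exon transcript a clean ORF: ATG at cds_start,
    no in-frame stop until a planted terminal TAA near the end of the last exon."""
    positions = np.concatenate([np.arange(s, e) for s, e in exons])
    tlen = len(positions)
    cds_t = int(np.searchsorted(positions, cds_start))
    if positions[cds_t] != cds_start:
        raise ValueError("cds_start not exonic")
    _plant(seq, cds_start, "ATG", protected)
    # terminal stop codon, leaving ~60 nt of 3' trailer
    n_codons = (tlen - 60 - cds_t) // 3
    stop_t = cds_t + 3 * (n_codons - 1)
    stop_pos = [int(positions[stop_t + k]) for k in range(3)]
    for p, b in zip(stop_pos, "TAA"):
        seq[p] = b
        protected.add(p)
    # remove every earlier in-frame stop
    for t in range(cds_t, stop_t, 3):
        codon_pos = [int(positions[t + k]) for k in range(3)]
        codon = "".join(seq[p] for p in codon_pos)
        if codon in STOP_CODONS:
            for k in (2, 1, 0):
                p = codon_pos[k]
                if p in protected:
                    continue
                for b in BASES:
                    trial = codon[:k] + b + codon[k + 1:]
                    if trial not in STOP_CODONS:
                        seq[p] = b
                        codon = trial
                        break
                break
            else:
                raise ValueError("cannot clean in-frame stop: codon protected")


# ---------------------------------------------------------------------------
# Edits
# ---------------------------------------------------------------------------

def apply_deletion(locus_or_allele: LocusModel | AlleleSequence, edit: EditSpec,
                   allele_id: str = "del_allele") -> AlleleSequence:
    """Delete ``[start, end)`` (± ``margin_indel`` bp at the right margin)."""
    if edit.kind != "deletion":
        raise ValueError("apply_deletion requires a deletion EditSpec")
    base = _as_allele(locus_or_allele, allele_id)
    L = len(base.sequence)
    if not (0 <= edit.start <= edit.end <= L):
        raise ValueError(f"deletion [{edit.start},{edit.end}) out of range")
    start = edit.start
    end = min(L, max(start, edit.end + edit.margin_indel))
    sequence = base.sequence[:start] + base.sequence[end:]
    new_map = [(0, start, 0), (start, L - (end - start), end)]
    new_map = [seg for seg in new_map if seg[0] < seg[1]]
    return AlleleSequence(
        sequence=sequence,
        edits=base.edits + [edit],
        segments=_compose(new_map, base.segments),
        allele_id=allele_id,
    )


def apply_tandem_duplication(locus_or_allele: LocusModel | AlleleSequence,
                             edit: EditSpec,
                             allele_id: str = "dup_allele") -> AlleleSequence:
    """Duplicate ``[start, end)`` head-to-tail: out = in[0:end] + in[start:].

    The novel junction joins input position ``end`` back to ``start``; the
    junction-crossing 20-mer is in[end-10:end] + in[start:start+10].
    """
    if edit.kind != "tandem_duplication":
        raise ValueError("apply_tandem_duplication requires a tandem_duplication EditSpec")
    base = _as_allele(locus_or_allele, allele_id)
    L = len(base.sequence)
    start, end = edit.start, edit.end
    if not (0 <= start < end <= L):
        raise ValueError(f"duplication [{start},{end}) out of range")
    span = end - start
    sequence = base.sequence[:end] + base.sequence[start:]
    new_map = [(0, end, 0), (end, end + span, start), (end + span, L + span, end)]
    new_map = [seg for seg in new_map if seg[0] < seg[1]]
    return AlleleSequence(
        sequence=sequence,
        edits=base.edits + [edit],
        segments=_compose(new_map, base.segments),
        allele_id=allele_id,
    )


def make_idfl_allele(locus: LocusModel,
                     margin_indel: int = 0) -> AlleleSequence:
    """Enhancer deletion followed by the default 24-kb tandem duplication."""
    cfg = DEFAULT_CONFIG
    del_edit = EditSpec("deletion", *locus.enhancer, margin_indel=margin_indel)
    allele = apply_deletion(locus, del_edit, allele_id="edel")
    # duplication span in reference coords -> allele coords after the deletion
    ref_s, ref_e = cfg["duplication"]["start"], cfg["duplication"]["end"]
    del_len = len(locus.sequence) - len(allele.sequence)
    dup_edit = EditSpec("tandem_duplication", ref_s - del_len, ref_e - del_len,
                        planted_microhomology=(3, 0))
    return apply_tandem_duplication(allele, dup_edit, allele_id="idfl")


def make_edel_allele(locus: LocusModel, margin_indel: int = 0) -> AlleleSequence:
    """Enhancer deletion only (on-target edit without the bystander)."""
    edit = EditSpec("deletion", *locus.enhancer, margin_indel=margin_indel)
    return apply_deletion(locus, edit, allele_id="edel")


# ---------------------------------------------------------------------------
# WGS read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadPair:
    read1: str
    read2: str
    fragment_start: int
    fragment_length: int
    source_allele: str


@dataclass
class ReadPairSet:
    pairs: list[ReadPair]
    read_length: int
    fragment_mean: float
    fragment_sd: float
    error_rate: float
    seed: int

    def __len__(self) -> int:
        return len(self.pairs)


def simulate_wgs_readpairs(allele: AlleleSequence | LocusModel,
                           depth: float = 30.0,
                           read_length: int = 150,
                           fragment_mean: float = 400.0,
                           fragment_sd: float = 60.0,
                           error_rate: float = 0.001,
                           seed: int = 0) -> ReadPairSet:
    """Simulate FR paired-end reads at the requested mean depth.

    Pair count is round(depth * L / (2 * read_length)); fragment lengths are
    normal(fragment_mean, fragment_sd) truncated to [2*read_length, L] and
    fragment starts are uniform. read2 is the reverse complement of the
    fragment 3' end. Substitution errors only.
    """
    allele = _as_allele(allele, "ref")
    seq = allele.sequence
    L = len(seq)
    if depth <= 0:
        raise ValueError("depth must be positive")
    if fragment_mean < 2 * read_length:
        raise ValueError("fragment_mean must be >= 2 * read_length")
    if L < fragment_mean + 4 * fragment_sd:
        raise ValueError("allele shorter than fragment_mean + 4*sd")
    n = int(round(depth * L / (2 * read_length)))
    rng = np.random.default_rng(seed)

    lo, hi = 2 * read_length, L
    lengths = np.rint(rng.normal(fragment_mean, fragment_sd, size=n)).astype(int)
    bad = (lengths < lo) | (lengths > hi)
    while bad.any():
        lengths[bad] = np.rint(
            rng.normal(fragment_mean, fragment_sd, size=int(bad.sum()))
        ).astype(int)
        bad = (lengths < lo) | (lengths > hi)
    starts = rng.integers(0, L - lengths + 1)

    err1 = _error_positions(rng, n, read_length, error_rate)
    err2 = _error_positions(rng, n, read_length, error_rate)

    pairs = []
    for i in range(n):
        s, flen = int(starts[i]), int(lengths[i])
        frag = seq[s:s + flen]
        r1 = _mutate(frag[:read_length], err1.get(i, ()), rng)
        r2 = _mutate(revcomp(frag[-read_length:]), err2.get(i, ()), rng)
        pairs.append(ReadPair(r1, r2, s, flen, allele.allele_id))
    return ReadPairSet(pairs, read_length, fragment_mean, fragment_sd,
                       error_rate, seed)


def _error_positions(rng: np.random.Generator, n: int, rl: int,
                     rate: float) -> dict[int, tuple[int, ...]]:
    if rate <= 0:
        return {}
    mask = rng.random((n, rl)) < rate
    rows, cols = np.nonzero(mask)
    out: dict[int, list[int]] = {}
    for r, c in zip(rows.tolist(), cols.tolist()):
        out.setdefault(r, []).append(c)
    return {k: tuple(v) for k, v in out.items()}


def _mutate(read: str, positions: Iterable[int], rng: np.random.Generator) -> str:
    read = list(read)
    for p in positions:
        read[p] = BASES[(BASES.index(read[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(read)


def merge_readpair_sets(sets: Sequence[ReadPairSet]) -> ReadPairSet:
    """Concatenate read sets from different haplotypes (same library params)."""
    first = sets[0]
    pairs = [p for s in sets for p in s.pairs]
    return ReadPairSet(pairs, first.read_length, first.fragment_mean,
                       first.fragment_sd, first.error_rate, first.seed)


# ---------------------------------------------------------------------------
# RNA junction-read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionContext:
    label: str
    sequence: str
    kmer_start: int

    @property
    def kmer(self) -> str:
        return self.sequence[self.kmer_start:self.kmer_start + 20]


def default_junction_contexts(flank: int = 80, seed: int = 99) -> list[JunctionContext]:
    """Transcript contexts embedding the packaged E2-E2 and E2-E3 20-mers."""
    rng = np.random.default_rng(seed)
    out = []
    kmers = {"E2E2": E2E2_KMER, "E2E3": E2E3_KMER}
    for label, kmer in kmers.items():
        while True:
            ctx = random_dna(flank, rng) + kmer + random_dna(flank, rng)
            others = [k for l, k in kmers.items() if l != label]
            if ctx.count(kmer) == 1 and not any(o in ctx for o in others):
                break
        out.append(JunctionContext(label, ctx, flank))
    return out


@dataclass
class RnaReadSet:
    reads: list[tuple[str, str]]  # (label, sequence)
    read_length: int
    seed: int

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for label, _ in self.reads:
            out[label] = out.get(label, 0) + 1
        return out


def simulate_rnaseq_reads(contexts: Sequence[JunctionContext] | None,
                          proportions: Mapping[str, float],
                          n_reads: int,
                          read_length: int = 75,
                          seed: int = 0) -> RnaReadSet:
    """Draw junction-spanning reads multinomially across labels.

    Every read fully contains its label's junction 20-mer. Labels missing
    from ``proportions`` get probability zero.
    """
    if contexts is None:
        contexts = default_junction_contexts()
    contexts = [c for c in contexts if proportions.get(c.label, 0) > 0]
    if not contexts:
        raise ValueError("no junction labels with positive proportion")
    if read_length < 20:
        raise ValueError("read_length must cover the 20-mer")
    probs = np.array([proportions[c.label] for c in contexts], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(contexts), size=n_reads, p=probs)
    reads = []
    for idx in picks.tolist():
        ctx = contexts[idx]
        lo = max(0, ctx.kmer_start + 20 - read_length)
        hi = min(len(ctx.sequence) - read_length, ctx.kmer_start)
        if hi < lo:
            raise ValueError(f"context for {ctx.label} too short for read_length")
        start = int(rng.integers(lo, hi + 1))
        reads.append((ctx.label, ctx.sequence[start:start + read_length]))
    return RnaReadSet(reads, read_length, seed)


# ---------------------------------------------------------------------------
# Cohort variants
# ---------------------------------------------------------------------------

VALID_GENOTYPES = {"0/0", "0/1", "1/1", "./."}


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 0-based internally
    ref: str
    alts: tuple[str, ...]
    genotypes: tuple[str, ...]  # per sample, same order as table.samples
    depths: tuple[int, ...]
    category: str = ""


@dataclass
class CohortVariantTable:
    records: list[VariantRecord]
    samples: list[str]
    affected_sample: str

    def __post_init__(self) -> None:
        if self.affected_sample not in self.samples:
            raise ValueError(f"affected sample {self.affected_sample!r} not in cohort")
        self.records.sort(key=lambda r: (r.chrom, r.pos))


@dataclass(frozen=True)
class PlannedVariant:
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    category: str  # private | shared | background | low_depth | multiallelic | non_exonic
    depth: int = 30


def emit_cohort_vcf(plan: Sequence[PlannedVariant],
                    samples: Sequence[str],
                    affected_sample: str,
                    contig: str = "synthetic_locus",
                    contig_length: int = 100_000) -> tuple[CohortVariantTable, str]:
    """Materialize a planted variant plan as a table plus VCF 4.2 text."""
    positions = [p.pos for p in plan]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate positions in variant plan")
    records = []
    for pv in plan:
        if not 0 <= pv.pos < contig_length:
            raise ValueError(f"variant position {pv.pos} outside contig")
        gts = []
        for s in samples:
            if pv.category == "shared":
                gts.append("0/1")
            elif pv.category == "missing_gt" and s != affected_sample:
                gts.append("./.")
            elif s == affected_sample:
                gts.append("0/1")
            else:
                gts.append("0/0")
        records.append(VariantRecord(
            chrom=contig, pos=pv.pos, ref=pv.ref, alts=tuple(pv.alts),
            genotypes=tuple(gts),
            depths=tuple(pv.depth for _ in samples),
            category=pv.category,
        ))
    table = CohortVariantTable(records, list(samples), affected_sample)
    return table, cohort_table_to_vcf(table, contig, contig_length)


def cohort_table_to_vcf(table: CohortVariantTable, contig: str,
                        contig_length: int) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={contig_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(table.samples),
    ]
    for r in table.records:
        fields = [r.chrom, str(r.pos + 1), ".", r.ref, ",".join(r.alts),
                  ".", "PASS", ".", "GT:DP"]
        fields += [f"{gt}:{dp}" for gt, dp in zip(r.genotypes, r.depths)]
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def cohort_table_from_vcf(path: str | Path, affected_sample: str) -> CohortVariantTable:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            gts, dps = [], []
            for s in samples:
                call = rec.samples[s]
                alleles = call.get("GT", (None, None))
                if alleles is None or any(a is None for a in alleles):
                    gts.append("./.")
                else:
                    gts.append("/".join(str(a) for a in sorted(alleles)))
                dps.append(int(call.get("DP") or 0))
            records.append(VariantRecord(
                chrom=rec.chrom, pos=rec.pos - 1, ref=rec.ref,
                alts=tuple(rec.alts or ()),
                genotypes=tuple(gts), depths=tuple(dps),
            ))
    return CohortVariantTable(records, samples, affected_sample)


def default_cohort_plan(locus: LocusModel, seed: int = 7) -> list[PlannedVariant]:
    """A small cohort plan exercising every filter stage: one private exonic
    "bystander" variant plus shared/background/low-depth/multiallelic/
    non-exonic decoys."""
    rng = np.random.default_rng(seed)
    exon = locus.exons[3]

    def base_at(pos: int) -> str:
        return locus.sequence[pos]

    def alt_for(pos: int) -> str:
        return _different_base(base_at(pos))

    positions = {
        "private": exon[0] + 20,
        "shared": exon[0] + 60,
        "low_depth": exon[0] + 90,
        "multiallelic": exon[1] - 10,
        "background": locus.exons[4][0] + 15,
        "non_exonic": exon[1] + 500,
        "missing_gt": locus.exons[4][0] + 40,
    }
    plan = []
    for cat, pos in positions.items():
        ref = base_at(pos)
        alts = (alt_for(pos),)
        if cat == "multiallelic":
            third = [b for b in BASES if b not in (ref, alts[0])][0]
            alts = (alts[0], third)
        plan.append(PlannedVariant(pos=pos, ref=ref, alts=alts, category=cat,
                                  depth=5 if cat == "low_depth" else 30))
    del rng
    return plan


# ---------------------------------------------------------------------------
# Off-target site plumbing
# ---------------------------------------------------------------------------

def make_offtarget_sites(contig: str, contig_length: int,
                         grna_ids: Sequence[str] = ("gRNA_L", "gRNA_R"),
                         n_per_grna: int = 49, seed: int = 11) -> list[tuple]:
    """Random predicted off-target cut sites: (contig, position, gRNA, rank)."""
    rng = np.random.default_rng(seed)
    sites = []
    for gid in grna_ids:
        positions = sorted(rng.choice(contig_length, size=n_per_grna,
                                      replace=False).tolist())
        for rank, pos in enumerate(positions, start=1):
            sites.append((contig, int(pos), gid, rank))
    return sites


def write_sites_tsv(sites: Sequence[tuple], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tposition\tgRNA\trank\n")
        for contig, pos, gid, rank in sites:
            fh.write(f"{contig}\t{pos}\t{gid}\t{rank}\n")


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_fasta(path: str | Path, name: str, sequence: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")


def write_fastq_pair(rps: ReadPairSet, prefix: str | Path) -> tuple[Path, Path]:
    """Write `_1.fastq` / `_2.fastq`; read names carry truth provenance."""
    prefix = Path(prefix)
    p1, p2 = Path(f"{prefix}_1.fastq"), Path(f"{prefix}_2.fastq")
    qual = "I" * rps.read_length
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for i, pr in enumerate(rps.pairs):
            name = f"pair{i}|{pr.source_allele}|{pr.fragment_start}|{pr.fragment_length}"
            f1.write(f"@{name}/1\n{pr.read1}\n+\n{qual}\n")
            f2.write(f"@{name}/2\n{pr.read2}\n+\n{qual}\n")
    return p1, p2


def write_rna_fastq(reads: RnaReadSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for i, (label, seq) in enumerate(reads.reads):
            fh.write(f"@rna{i}|{label}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


def write_bed(path: str | Path, contig: str,
              intervals: Sequence[tuple[int, int, str]]) -> None:
    with open(path, "w") as fh:
        for start, end, name in intervals:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\n")


def truth_json(locus: LocusModel, alleles: Sequence[AlleleSequence]) -> dict:
    """Machine-readable truth annotations for downstream assertions."""
    cfg = DEFAULT_CONFIG
    dup = cfg["duplication"]
    mh = cfg["microhomology"]
    ref = locus.sequence
    s, e = mh["s"], mh["e"]
    return {
        "locus": {"name": locus.name, "length": len(ref),
                  "enhancer": list(locus.enhancer),
                  "exons": [list(x) for x in locus.exons],
                  "cut_sites": dict(locus.cut_sites)},
        "duplication": {"start": dup["start"], "end": dup["end"],
                        "span": dup["end"] - dup["start"],
                        "microhomology_left": mh["mL"],
                        "microhomology_right": mh["mR"],
                        "junction_20mer": ref[e - 10:e] + ref[s:s + 10]},
        "alleles": [
            {"id": a.allele_id, "length": len(a.sequence),
             "edits": [dataclasses.asdict(ed) for ed in a.edits]}
            for a in alleles
        ],
        "splice_kmers": {"E2E2": E2E2_KMER, "E2E3": E2E3_KMER},
    }
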