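"""Splice-junction k-mer quantification, isoform enumeration with
premature-stop classification, and in-silico PCR genotyping."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .locus_forge import AlleleSequence, LocusModel
from .sequtil import is_dna, revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# Junction k-mer counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionKmerCount:
    label: str
    kmer: str
    count: int
    total_reads: int

    @property
    def normalized(self) -> float:
        return self.count / self.total_reads if self.total_reads else 0.0


def iter_fastq_sequences(paths: Sequence[str | Path]) -> Iterable[str]:
    import pysam

    for path in paths:
        with pysam.FastxFile(str(path)) as fx:
            for entry in fx:
                yield entry.sequence


def count_junction_kmers(
    reads: Iterable[str],
    kmers: Mapping[str, str],
    count_reverse_complement: bool = False,
    ratio_labels: tuple[str, str] | None = None,
) -> tuple[list[JunctionKmerCount], float | None]:
    """Count reads containing each labeled k-mer as an exact substring.

    A read counts at most once per label even if the k-mer occurs twice.
    Reverse-complement matching is off by default (raw-text grep semantics).
    When ``ratio_labels=(a, b)`` is given, also return count(a)/count(b)
    (None when count(b) is zero: the ratio is undefined).
    """
    if not kmers:
        raise ValueError("k-mer set must be non-empty")
    for label, km in kmers.items():
        if not is_dna(km):
            raise ValueError(f"k-mer for {label!r} must be uppercase A/C/G/T")
    probes = {
        label: (km, revcomp(km)) if count_reverse_complement else (km,)
        for label, km in kmers.items()
    }
    counts = {label: 0 for label in kmers}
    total = 0
    for read in reads:
        total += 1
        for label, pats in probes.items():
            if any(p in read for p in pats):
                counts[label] += 1
    results = [JunctionKmerCount(label, kmers[label], counts[label], total)
               for label in kmers]
    ratio = None
    if ratio_labels is not None:
        a, b = ratio_labels
        ratio = counts[a] / counts[b] if counts[b] else None
    return results, ratio


# ---------------------------------------------------------------------------
# Isoform enumeration / premature-stop classification
# ---------------------------------------------------------------------------

@dataclass
class SplicedGeneModel:
    """Exon sequences plus a canonical chain and an annotated CDS start.

    ``cds_exon``/``cds_offset`` locate the start codon inside an exon, which
    keeps the annotation valid across chains that repeat other exons.
    """

    exons: dict[str, str]
    canonical_chain: list[str]
    cds_exon: str
    cds_offset: int

    @classmethod
    def from_locus(cls, locus: LocusModel) -> "SplicedGeneModel":
        if locus.cds_start is None:
            raise ValueError("locus has no annotated CDS start")
        exons = {f"E{i}": locus.exon_sequence(i)
                 for i in range(1, len(locus.exons) + 1)}
        chain = list(exons)
        cds_exon = None
        for i, (s, e) in enumerate(locus.exons, start=1):
            if s <= locus.cds_start < e:
                cds_exon, cds_offset = f"E{i}", locus.cds_start - s
        if cds_exon is None:
            raise ValueError("cds_start not inside an exon")
        return cls(exons, chain, cds_exon, cds_offset)

    def mrna(self, chain: Sequence[str]) -> str:
        return "".join(self.exons[e] for e in chain)

    def cds_start_in(self, chain: Sequence[str]) -> int:
        offset = 0
        for e in chain:
            if e == self.cds_exon:
                return offset + self.cds_offset
            offset += len(self.exons[e])
        raise ValueError(f"chain lacks CDS exon {self.cds_exon}")


@dataclass
class IsoformCall:
    chain: list[str]
    mrna: str
    protein: str  # translated prefix up to (excluding) the first stop
    classification: str  # productive | premature_stop
    stop_codon_index: int | None = None  # 1-based codon index of a premature stop
    nmd_candidate: bool = False


def _first_stop(mrna: str, start: int) -> tuple[int | None, str]:
    """(codon index of first in-frame stop, translated prefix)."""
    frame = mrna[start:start + 3 * ((len(mrna) - start) // 3)]
    protein = str(Seq(frame).translate(to_stop=True))
    idx = len(protein)  # codons before the stop
    if start + 3 * idx + 3 <= len(mrna) and \
            mrna[start + 3 * idx:start + 3 * idx + 3] in STOP_CODONS:
        return idx, protein
    return None, protein


def _annotated_stop_exon(model: SplicedGeneModel) -> tuple[str, int]:
    """Locate the canonical terminal stop as (exon id, offset of its last base)."""
    chain = model.canonical_chain
    mrna = model.mrna(chain)
    start = model.cds_start_in(chain)
    idx, _ = _first_stop(mrna, start)
    if idx is None:
        raise ValueError("canonical chain has no terminal stop codon")
    last_base = start + 3 * idx + 2
    offset = 0
    for e in chain:
        if offset <= last_base < offset + len(model.exons[e]):
            return e, last_base - offset
        offset += len(model.exons[e])
    raise AssertionError("stop position outside transcript")


def classify_chain(model: SplicedGeneModel, chain: Sequence[str]) -> IsoformCall:
    """Splice, translate, and classify one exon chain.

    premature_stop iff the first in-frame stop lies strictly 5' of where the
    annotated terminal stop falls in this chain (mapped through the last
    occurrence of the stop-bearing exon). The 50-nt NMD rule is annotated
    only, never used for classification.
    """
    mrna = model.mrna(chain)
    start = model.cds_start_in(chain)
    if mrna[start:start + 3] != "ATG":
        raise ValueError("start codon absent at annotated CDS start")
    stop_exon, stop_off = _annotated_stop_exon(model)
    # terminal-stop position in this chain: last occurrence of the stop exon
    offset, terminal_last_base = 0, None
    for e in chain:
        if e == stop_exon:
            terminal_last_base = offset + stop_off
        offset += len(model.exons[e])
    idx, protein = _first_stop(mrna, start)
    stop_last_base = start + 3 * idx + 2 if idx is not None else None
    premature = (
        stop_last_base is not None
        and terminal_last_base is not None
        and stop_last_base < terminal_last_base
    )
    nmd = False
    if premature:
        last_junction = len(mrna) - len(model.exons[chain[-1]])
        nmd = stop_last_base < last_junction - 50
    return IsoformCall(
        chain=list(chain), mrna=mrna, protein=protein,
        classification="premature_stop" if premature else "productive",
        stop_codon_index=(idx + 1) if premature else None,
        nmd_candidate=nmd,
    )


def enumerate_isoforms_and_classify(model: SplicedGeneModel,
                                    duplicated_exon: str = "E2") -> list[IsoformCall]:
    """Chains for an allele carrying ``duplicated_exon`` twice: the
    both-copies chain and the single-copy (exon-skipping) chain."""
    if duplicated_exon not in model.exons:
        raise ValueError(f"unknown exon {duplicated_exon!r}")
    single = list(model.canonical_chain)
    double = []
    for e in model.canonical_chain:
        double.append(e)
        if e == duplicated_exon:
            double.append(e)
    return [classify_chain(model, double), classify_chain(model, single)]


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmpliconCall:
    pair_id: str
    allele_id: str
    product_length: int | None
    status: str  # product | no_product | ambiguous
    genotype_label: str = ""


def insilico_pcr(allele: AlleleSequence | LocusModel | str,
                 forward_primer: str, reverse_primer: str,
                 max_product: int = 2000, pair_id: str = "assay") -> AmpliconCall:
    """Predict the PCR product of a convergent primer pair on one allele.

    Product length = (reverse-primer 3' end) - (forward-primer 5' start) for
    the unique convergent placement within ``max_product``; multiple candidate
    products give status "ambiguous".
    """
    if len(forward_primer) < 15 or len(reverse_primer) < 15:
        raise ValueError("primers must be >= 15 nt")
    if isinstance(allele, str):
        seq, allele_id = allele, "allele"
    elif isinstance(allele, LocusModel):
        seq, allele_id = allele.sequence, allele.name
    else:
        seq, allele_id = allele.sequence, allele.allele_id
    f_hits = _find_all(seq, forward_primer)
    r_hits = _find_all(seq, revcomp(reverse_primer))
    products = []
    for f in f_hits:
        for r in r_hits:
            length = r + len(reverse_primer) - f
            if r >= f + len(forward_primer) - len(reverse_primer) \
                    and length >= max(len(forward_primer), len(reverse_primer)) \
                    and length <= max_product:
                products.append(length)
    if not products:
        return AmpliconCall(pair_id, allele_id, None, "no_product")
    if len(products) > 1:
        return AmpliconCall(pair_id, allele_id, None, "ambiguous")
    return AmpliconCall(pair_id, allele_id, products[0], "product")


def genotype_label(call: AmpliconCall, wt_length: int) -> str:
    """Coarse genotype label from a product-length comparison with wild type."""
    if call.status != "product":
        return call.status
    delta = wt_length - call.product_length
    if delta == 0:
        return "wt"
    if delta > 0:
        return f"deletion_{delta}bp"
    return f"insertion_{-delta}bp"


def _find_all(text: str, pattern: str) -> list[int]:
    out, start = [], 0
    while True:
        i = text.find(pattern, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def write_count_table(counts: Sequence[JunctionKmerCount], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("label\tkmer\tcount\ttotal\tnormalized\n")
        for c in counts:
            fh.write(f"{c.label}\t{c.kmer}\t{c.count}\t{c.total_reads}"
                     f"\t{c.normalized:.6g}\n")
    return path
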