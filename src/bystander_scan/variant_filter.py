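"""Candidate-variant searches for an edited-founder cohort.

Two screens: a biased scan for variants within a few bp of predicted
off-target cut sites, and an unbiased inheritance-model filter that keeps
biallelic, fully genotyped, well-covered variants that are unique to (or in
excess in) the affected sample, absent from the strain background panel,
and exonic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .locus_forge import CohortVariantTable, VariantRecord

BackgroundKey = tuple[str, int, str, str]  # chrom, pos (0-based), ref, alt


@dataclass(frozen=True)
class OffTargetSite:
    grna_id: str
    contig: str
    cut_pos: int  # 0-based
    rank: int

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


def read_sites_tsv(path: str | Path) -> list[OffTargetSite]:
    """Load predicted off-target sites from a (contig, position, gRNA, rank) TSV."""
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sites.append(OffTargetSite(
                grna_id=f[cols["gRNA"]], contig=f[cols["contig"]],
                cut_pos=int(f[cols["position"]]), rank=int(f[cols["rank"]])))
    return sites


def offtarget_proximity_filter(
    variants: CohortVariantTable,
    sites: Sequence[OffTargetSite],
    flank: int = 5,
    background: set[BackgroundKey] | None = None,
) -> tuple[list[VariantRecord], list[bool]]:
    """Select variants within ``flank`` bp (inclusive) of any predicted cut
    site, and flag each selection for background-panel membership."""
    background = background or set()
    selected, flags = [], []
    for rec in variants.records:
        near = any(rec.chrom == site.contig and abs(rec.pos - site.cut_pos) <= flank
                   for site in sites)
        if near:
            selected.append(rec)
            flags.append(any((rec.chrom, rec.pos, rec.ref, alt) in background
                             for alt in rec.alts))
    return selected, flags


@dataclass
class FilterTrace:
    input: int
    after_biallelic: int
    after_genotyped: int
    after_coverage: int
    after_affected_excess: int
    after_background_subtraction: int
    after_exonic: int

    def counts(self) -> list[int]:
        return [self.input, self.after_biallelic, self.after_genotyped,
                self.after_coverage, self.after_affected_excess,
                self.after_background_subtraction, self.after_exonic]


def alt_allele_count(genotype: str) -> int:
    """Number of alternate alleles in a diploid genotype string; missing -> 0."""
    if genotype in ("./.", ".", ""):
        return 0
    return sum(1 for a in genotype.replace("|", "/").split("/") if a == "1")


def _is_biallelic_snp_or_indel(rec: VariantRecord) -> bool:
    if len(rec.alts) != 1:
        return False
    alt = rec.alts[0]
    ok = set(rec.ref) <= set("ACGT") and set(alt) <= set("ACGT")
    return ok and alt != rec.ref and len(rec.ref) >= 1 and len(alt) >= 1


def _overlaps_exon(rec: VariantRecord, exonic: Sequence[tuple[int, int]]) -> bool:
    v_start, v_end = rec.pos, rec.pos + len(rec.ref)
    return any(v_start < e and s < v_end for s, e in exonic)


def cohort_inheritance_filter(
    variants: CohortVariantTable,
    affected: str,
    background: set[BackgroundKey] | None = None,
    exonic: Sequence[tuple[int, int]] = (),
    min_avg_depth: float = 10.0,
    per_sample_min_depth: float | None = None,
) -> tuple[list[VariantRecord], FilterTrace]:
    """Six-stage inheritance-model filter.

    Stages, applied in order: (1) biallelic SNP/INDEL only; (2) every sample
    genotyped; (3) mean depth across samples >= min_avg_depth (optionally a
    per-sample floor instead); (4) affected alt-allele count strictly exceeds
    every other sample's; (5) not in the background panel (pos+ref+alt match);
    (6) overlaps an exonic interval. Returns survivors plus per-stage counts.
    """
    if affected not in variants.samples:
        raise ValueError(f"affected sample {affected!r} not in cohort")
    background = background or set()
    aff_idx = variants.samples.index(affected)
    other_idx = [i for i, s in enumerate(variants.samples) if s != affected]

    pool = list(variants.records)
    n0 = len(pool)

    pool = [r for r in pool if _is_biallelic_snp_or_indel(r)]
    n1 = len(pool)

    pool = [r for r in pool if all(gt != "./." for gt in r.genotypes)]
    n2 = len(pool)

    if per_sample_min_depth is not None:
        pool = [r for r in pool
                if all(dp >= per_sample_min_depth for dp in r.depths)]
    else:
        pool = [r for r in pool
                if sum(r.depths) / len(r.depths) >= min_avg_depth]
    n3 = len(pool)

    pool = [r for r in pool
            if alt_allele_count(r.genotypes[aff_idx])
            > max((alt_allele_count(r.genotypes[i]) for i in other_idx), default=0)]
    n4 = len(pool)

    pool = [r for r in pool
            if (r.chrom, r.pos, r.ref, r.alts[0]) not in background]
    n5 = len(pool)

    pool = [r for r in pool if _overlaps_exon(r, exonic)]
    n6 = len(pool)

    trace = FilterTrace(n0, n1, n2, n3, n4, n5, n6)
    return pool, trace


# ---------------------------------------------------------------------------
# Background panel / BED input
# ---------------------------------------------------------------------------

def background_from_vcf(path: str | Path) -> set[BackgroundKey]:
    import pysam

    keys: set[BackgroundKey] = set()
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                keys.add((rec.chrom, rec.pos - 1, rec.ref, alt))
    return keys


def background_from_table(records: Iterable[VariantRecord]) -> set[BackgroundKey]:
    keys: set[BackgroundKey] = set()
    for rec in records:
        for alt in rec.alts:
            keys.add((rec.chrom, rec.pos, rec.ref, alt))
    return keys


def read_bed_intervals(path: str | Path,
                       contig: str | None = None) -> list[tuple[int, int]]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            f = line.split("\t")
            if len(f) < 3 or (contig is not None and f[0] != contig):
                continue
            intervals.append((int(f[1]), int(f[2])))
    return intervals
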