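"""End-to-end orchestration: simulate -> align -> depth -> SV -> filter ->
isoform, with a machine-readable run report and stage resume."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__, align_depth, isoform, locus_forge, sv_breakpoint, variant_filter

log = logging.getLogger("bystander_scan")

STAGES = ("simulate", "depth", "sv", "filter", "isoform")


@dataclass
class RunConfig:
    seed: int = 1
    zygosity: str = "hom"  # hom | het | control
    depth: float = 30.0
    read_length: int = 150
    fragment_mean: float = 400.0
    fragment_sd: float = 60.0
    error_rate: float = 0.001
    window: int = 500
    threshold: float = 1.4
    min_windows: int = 5
    max_gap: int = 1
    assembly_k: int = 31
    min_support: int = 3
    min_clip: int = 20
    flank: int = 5
    min_avg_depth: float = 10.0
    rna_reads: int = 11000
    rna_read_length: int = 75
    rna_seed: int = 7
    rna_proportions: dict = field(
        default_factory=lambda: {"E2E3": 10 / 11, "E2E2": 1 / 11})
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    locus_config: dict | None = None
    resume: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.zygosity not in ("hom", "het", "control"):
            raise ValueError(f"unknown zygosity {cfg.zygosity!r}")
        stages = {s: True for s in STAGES}
        stages.update(cfg.stages or {})
        unknown_stages = set(stages) - set(STAGES)
        if unknown_stages:
            raise ValueError(f"unknown stages: {sorted(unknown_stages)}")
        cfg.stages = stages
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _haplotypes(locus: locus_forge.LocusModel, zygosity: str):
    ref_allele = locus_forge.AlleleSequence(
        locus.sequence, [], [(0, len(locus.sequence), 0)], allele_id="wt")
    idfl = locus_forge.make_idfl_allele(locus)
    edel = locus_forge.make_edel_allele(locus)
    if zygosity == "hom":
        return [idfl, idfl]
    if zygosity == "het":
        return [idfl, edel]
    return [ref_allele, ref_allele]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages in dependency order; returns the report.

    Stage outputs land in ``out_dir``; an existing alignments.sam is reused
    when ``config.resume`` is set. The report is written atomically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    report: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "blocks": None, "junction": None, "microhomology": None,
        "filter_trace": None, "isoform_counts": None,
        "truth_comparison": None,
    }
    locus = locus_forge.build_locus(config.locus_config)
    truth = None
    records = None
    rps = None

    if config.stages["simulate"]:
        log.info("stage simulate: zygosity=%s depth=%.1fx", config.zygosity,
                 config.depth)
        haplotypes = _haplotypes(locus, config.zygosity)
        sets = []
        for i, allele in enumerate(haplotypes):
            sets.append(locus_forge.simulate_wgs_readpairs(
                allele, depth=config.depth / len(haplotypes),
                read_length=config.read_length,
                fragment_mean=config.fragment_mean,
                fragment_sd=config.fragment_sd,
                error_rate=config.error_rate,
                seed=config.seed + i))
        rps = locus_forge.merge_readpair_sets(sets)
        locus_forge.write_fasta(out / "reference.fasta", locus.name, locus.sequence)
        locus_forge.write_fastq_pair(rps, out / "reads")
        truth = locus_forge.truth_json(locus, haplotypes)
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
        report["stages"]["simulate"] = {
            "n_pairs": len(rps), "alleles": [a.allele_id for a in haplotypes]}

    if config.stages["depth"] or config.stages["sv"]:
        sam_path = out / "alignments.sam"
        if config.resume and sam_path.exists():
            log.info("stage align: reusing %s", sam_path)
            records, _, _ = align_depth.read_sam(sam_path)
        else:
            if rps is None:
                raise RuntimeError("depth/sv stages need simulated reads or an "
                                   "existing alignments.sam")
            log.info("stage align: %d pairs", len(rps))
            index = align_depth.ReferenceIndex(locus.sequence, locus.name)
            records = align_depth.align_readpair_set(index, rps)
            align_depth.write_sam(records, locus.name, len(locus.sequence), sam_path)

    if config.stages["depth"]:
        profile = align_depth.compute_coverage_profile(
            records, len(locus.sequence), config.window)
        blocks = align_depth.detect_elevated_blocks(
            profile, config.threshold, config.min_windows, config.max_gap)
        align_depth.write_coverage_tsv(profile, out / "coverage.tsv")
        try:
            median_tlen, mean_depth = align_depth.library_stats(
                records, len(locus.sequence))
        except ValueError:
            median_tlen, mean_depth = None, 0.0
        report["blocks"] = [dataclasses.asdict(b) for b in blocks]
        report["stages"]["depth"] = {
            "n_blocks": len(blocks), "median_template": median_tlen,
            "mean_depth": mean_depth}
        log.info("stage depth: %d elevated block(s)", len(blocks))

    if config.stages["sv"]:
        pair_counts = sv_breakpoint.classify_pairs(
            records, config.fragment_mean, config.fragment_sd)
        candidates = sv_breakpoint.recruit_candidate_reads(
            records, config.fragment_mean, config.fragment_sd, config.min_clip)
        junction_info: dict[str, Any]
        try:
            junction = sv_breakpoint.assemble_junction(
                candidates, locus.sequence, config.assembly_k, config.min_support)
            junction_info = {
                "status": "called",
                "left_break": junction.left_break,
                "right_break": junction.right_break,
                "orientation": junction.orientation,
                "microhomology_left": junction.microhomology_left,
                "microhomology_right": junction.microhomology_right,
                "microhomology_total": junction.microhomology_total,
                "inserted_sequence": junction.inserted_sequence,
                "support": junction.support,
                "contig_length": len(junction.contig),
            }
            (out / "junction.fasta").write_text(
                f">junction\n{junction.contig}\n")
            report["microhomology"] = junction.microhomology_total
            if locus.cut_sites:
                cut = min(locus.cut_sites.values(),
                          key=lambda c: abs(c - junction.left_break))
                segs = sv_breakpoint.scan_extended_homology(
                    locus.sequence, cut, junction.left_break,
                    junction.right_break)
                junction_info["extended_homology_segments"] = len(segs)
        except sv_breakpoint.NoJunctionError as err:
            junction_info = {"status": "no_junction", "detail": str(err)}
        except sv_breakpoint.AmbiguousJunctionError as err:
            junction_info = {"status": "ambiguous", "detail": str(err)}
        report["junction"] = junction_info
        report["stages"]["sv"] = {
            "pair_classes": pair_counts, "n_candidates": len(candidates)}
        log.info("stage sv: junction %s", junction_info["status"])

    if config.stages["filter"]:
        plan = locus_forge.default_cohort_plan(locus, seed=config.seed)
        samples = ["IDFL_hom", "IDFL_het", "Line2"]
        table, vcf_text = locus_forge.emit_cohort_vcf(
            plan, samples, "IDFL_hom", contig=locus.name,
            contig_length=len(locus.sequence))
        (out / "cohort.vcf").write_text(vcf_text)
        background = {(locus.name, p.pos, p.ref, p.alts[0])
                      for p in plan if p.category == "background"}
        survivors, trace = variant_filter.cohort_inheritance_filter(
            table, "IDFL_hom", background, locus.exons, config.min_avg_depth)
        sites = locus_forge.make_offtarget_sites(
            locus.name, len(locus.sequence), seed=config.seed)
        site_objs = [variant_filter.OffTargetSite(g, c, p, r)
                     for c, p, g, r in sites]
        near, flags = variant_filter.offtarget_proximity_filter(
            table, site_objs, config.flank, background)
        report["filter_trace"] = dataclasses.asdict(trace)
        report["stages"]["filter"] = {
            "survivors": [{"pos": r.pos, "ref": r.ref, "alts": list(r.alts),
                           "category": r.category} for r in survivors],
            "offtarget_proximal": len(near),
            "offtarget_background_flags": flags,
        }
        log.info("stage filter: %d survivor(s)", len(survivors))

    if config.stages["isoform"]:
        rna = locus_forge.simulate_rnaseq_reads(
            None, config.rna_proportions, config.rna_reads,
            config.rna_read_length, seed=config.rna_seed)
        locus_forge.write_rna_fastq(rna, out / "rna.fastq")
        counts, ratio = isoform.count_junction_kmers(
            (seq for _, seq in rna.reads),
            {"E2E2": locus_forge.E2E2_KMER, "E2E3": locus_forge.E2E3_KMER},
            ratio_labels=("E2E3", "E2E2"))
        calls = []
        if locus.cds_start is not None:
            model = isoform.SplicedGeneModel.from_locus(locus)
            calls = isoform.enumerate_isoforms_and_classify(model, "E2")
        report["isoform_counts"] = {
            c.label: {"kmer": c.kmer, "count": c.count,
                      "total": c.total_reads, "normalized": c.normalized}
            for c in counts}
        report["stages"]["isoform"] = {
            "ratio_E2E3_to_E2E2": ratio,
            "isoform_calls": [
                {"chain": c.chain, "classification": c.classification,
                 "stop_codon_index": c.stop_codon_index,
                 "nmd_candidate": c.nmd_candidate} for c in calls],
        }
        log.info("stage isoform: ratio=%s", ratio)

    if truth is not None:
        report["truth_comparison"] = _compare_truth(report, truth, config)
    write_report(report, out / "report.json")
    return report


def _compare_truth(report: dict, truth: dict, config: RunConfig) -> dict:
    cmp: dict[str, Any] = {}
    dup = truth["duplication"]
    if report.get("blocks"):
        block = max(report["blocks"], key=lambda b: b["end"] - b["start"])
        cmp["block_boundary_error_windows"] = max(
            abs(block["start"] - dup["start"]),
            abs(block["end"] - dup["end"])) / config.window
        cmp["block_length_error_bp"] = (
            (block["end"] - block["start"]) - dup["span"])
    junction = report.get("junction")
    if junction and junction.get("status") == "called":
        mh_total = dup["microhomology_left"] + dup["microhomology_right"]
        err_e = _ambiguity_distance(junction["left_break"], dup["end"], mh_total)
        err_s = _ambiguity_distance(junction["right_break"], dup["start"], mh_total)
        cmp["breakpoint_error_bp"] = max(err_e, err_s)
        cmp["microhomology_match"] = (
            junction["microhomology_total"] == mh_total)
    return cmp


def _ambiguity_distance(found: int, expected: int, ambiguity: int) -> int:
    """Distance outside the microhomology ambiguity interval."""
    lo, hi = expected - ambiguity, expected + ambiguity
    if lo <= found <= hi:
        return 0
    return min(abs(found - lo), abs(found - hi))


def write_report(report: dict, path: str | Path, fmt: str = "json") -> Path:
    """Serialize the run report atomically (write temp file, then rename)."""
    path = Path(path)
    validate_report(report)
    if fmt == "json":
        text = json.dumps(report, indent=2, sort_keys=True)
    elif fmt == "text":
        lines = [f"bystander-scan {report['version']}"]
        for stage, info in report["stages"].items():
            lines.append(f"[{stage}] {json.dumps(info, sort_keys=True)}")
        text = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)
    return path


REPORT_SCHEMA_KEYS = {"version", "config", "stages", "blocks", "junction",
                      "microhomology", "filter_trace", "isoform_counts",
                      "truth_comparison"}


def validate_report(report: dict) -> None:
    missing = REPORT_SCHEMA_KEYS - set(report)
    if missing:
        raise ValueError(f"report missing keys: {sorted(missing)}")
    json.dumps(report)  # must be serializable


def _setup_logging(out_dir: Path) -> None:
    if not log.handlers:
        fmt = logging.Formatter(
            "%(asctime)s %(levelname)s %(name)s: %(message)s")
        stream = logging.StreamHandler()
        stream.setFormatter(fmt)
        log.addHandler(stream)
        log.setLevel(logging.INFO)
    # one file handler per run directory; drop handlers from previous runs
    for handler in [h for h in log.handlers
                    if isinstance(h, logging.FileHandler)]:
        handler.close()
        log.removeHandler(handler)
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    log.addHandler(fh)
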