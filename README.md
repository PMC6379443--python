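# bystander-scan

Locus-scale detection and characterization of CRISPR "bystander" structural
variants — unintended rearrangements physically linked to an on-target edit.
The package reimplements, as a tested pipeline, the discovery analysis for a
tandem duplication adjacent to an enhancer deletion:

- **`locus_forge`** — synthetic-data generator: truth-annotated locus models
  (8-exon gene, 360-bp intronic enhancer, 24-kb duplication span with 3 nt of
  planted breakpoint microhomology), edited haplotypes with coordinate
  liftover, 150-bp paired-end WGS read simulation (FR, ~400-bp inserts),
  junction-spanning RNA read mixtures, and small cohort VCFs.
- **`align_depth`** — minimal seed-and-extend paired-end aligner (k-mer seeds,
  gapless scored extension with soft-clipping), windowed coverage ratios, and
  elevated-block (copy-gain) segmentation; SAM text I/O.
- **`sv_breakpoint`** — discordant-pair classification (everted pairs are the
  tandem-duplication signature), de Bruijn assembly of the junction contig
  from clipped reads and everted mates, base-pair breakpoint placement, and
  microhomology / extended-homology scans.
- **`variant_filter`** — the ±5-bp off-target proximity screen and the
  six-stage cohort inheritance-model filter (biallelic → genotyped →
  coverage → affected-excess → background subtraction → exonic).
- **`isoform`** — junction 20-mer read counting from FASTQ (grep semantics),
  splice-isoform enumeration with premature-stop classification for the
  duplicated-exon allele, and in-silico PCR genotyping.
- **`pipeline` / `cli`** — orchestration with YAML config, seeded
  reproducibility, stage resume, and a JSON run report with
  truth-comparison fields.

## CLI

```sh
# end-to-end seeded run (simulate -> align -> depth -> SV -> filter -> isoform)
bystander-scan run --out runs/demo --seed 1

# individual stages
bystander-scan simulate --out sim --seed 1 --zygosity hom
bystander-scan depth --ref sim/reference.fasta --reads sim/reads_1.fastq sim/reads_2.fastq --out depth_out
bystander-scan sv --ref sim/reference.fasta --sam depth_out/alignments.sam --out sv_out
bystander-scan filter-variants --vcf sim/cohort.vcf --affected IDFL_hom --exons exons.bed --out filt_out
bystander-scan isoform --fastq sim/rna.fastq
bystander-scan pcr --allele allele.fasta --primers primers.tsv
```

`bystander-scan run` writes a run directory containing the config echo,
logs, FASTA/FASTQ/SAM/VCF intermediates, and `report.json` (elevated blocks,
junction breakpoints and microhomology, filter trace, isoform counts, and —
when simulating — truth-comparison errors in bp/windows). Reports are
bit-identical for identical config + seed.

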