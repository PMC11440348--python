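# umicall

Ultrasensitive circulating tumor DNA (ctDNA) monitoring from UMI-tagged
amplicon sequencing, built around the hotspot panel used for ALK-driven
neuroblastoma (seven assays across the *ALK* tyrosine kinase domain, 351 bp
of target sequence, 20 catalogued hotspot and TKI-resistance mutations) plus
a single-assay *HRAS* p.Q61L resistance panel.

The package is for scientists analysing — or prototyping analyses of —
liquid-biopsy amplicon data in which every original cfDNA molecule is tagged
with a unique molecular identifier (UMI) before PCR. It covers the whole
chain: a ground-truth read simulator, UMI extraction and primer-anchored
read assignment, UMI-family consensus error correction, hotspot
quantification with single-molecule positivity and a per-sample limit of
detection, secondary-variant screening, and longitudinal minimal-residual-
disease (MRD) monitoring with relapse/clearance event calling.

## The method

Reads sharing a (target region, UMI) key form a **UMI family**, presumed
copies of one original molecule. Families with at least 3 raw reads yield an
error-corrected **consensus read**: at each position the base reaching a 60%
majority of covering members, else `N`. Errors introduced after the first
copy (later PCR cycles, the sequencer) are voted away; errors on the first
copy penetrate the consensus — the simulator's two error tiers encode
exactly this distinction, so tests can show what UMI correction can and
cannot remove.

For a tracked hotspot with mutant consensus count *m* among consensus depth
*N*:

- **VAF** = *m*/*N* (molecule counting — allele frequency over families,
  not raw reads, so amplification bias cancels);
- the sample is **ctDNA-positive** iff *m* ≥ 1;
- the per-sample **limit of detection** is the VAF of a single mutant
  molecule, LOD = 100/*N* percent — at the panel's mean hotspot consensus
  depth of 5,180 families this is 0.02%.

Nonsynonymous non-tracked variants at ≥ 1% consensus AF are reported as
secondary (resistance) candidates. Longitudinal series are classified
per sample (negative / low_positive = 1 molecule / positive ≥ 2 molecules)
and scanned for events: a molecular relapse needs a positive sample or a
confirmed low_positive; an isolated single-molecule sample among negatives
is flagged indeterminate, not relapse (`--strict-paper-positivity` restores
the plain binary ≥ 1-molecule rule).

## Worked example

Simulate an *HRAS* Q61 sample of 2,000 cfDNA molecules at a true VAF of 1%
with a 10⁻³ per-base late error rate, then call it:

```bash
umicall simulate --panel hras_q61 --molecules 2000 --vaf HRAS_Q61L=0.01 \
    --late-error-rate 0.001 --seed 4 -o demo.fastq
umicall consensus demo.fastq --panel hras_q61
# 2186 families, 1690 consensus reads, 496 below min size 3
umicall call demo.fastq --panel hras_q61 --tracked-hotspot HRAS_Q61L \
    --sample-id demo -o demo.vcf
# HRAS_Q61L  mutant=13  depth=1690  VAF=0.7692%  LOD=0.06%  positive=True
```

Of 2,000 molecules, 1,690 produced families of ≥ 3 reads; 13 of those
consensus reads carry the p.Q61L base, giving an estimated VAF of 0.77%
(truth 1%, within two binomial standard deviations at this depth) and a
single-molecule detection floor of 100/1690 ≈ 0.06% for this sample. The
VCF record carries the same numbers:

```
chr11  533907  .  T  A  .  .  MC=13;DP=1690;VAF_PCT=0.7692;LOD_PCT=0.06;PCHANGE=p.Q61L;...
```

Longitudinal monitoring takes a sample sheet (TSV: patient_id, sample_id,
collection_date, tracked_hotspot, fastq) and writes per-sample VCF/TSV, a
QC summary, and per-patient time-series and event tables:

```bash
umicall monitor sheet.tsv --panel hras_q61 -o out/
# events.tsv: pat1  molecular_relapse  2024-02-01  s1
```

The bundled NB-ALK panel file ships placeholder genomic coordinates and
flanking sequence (flagged in its header); amplicon sizes, total target
length and the hotspot codons themselves are faithful. Library calls mirror
the CLI one-to-one (`umicall.simulate_sample`, `process_fastq`,
`group_families`, `build_consensus`, `call_sample`, `build_time_series`).

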