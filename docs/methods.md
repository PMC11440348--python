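# Methods

## Scope and model

`umicall` implements molecule-counting mutation detection for UMI-tagged
amplicon panels. The object of inference is the variant allele frequency
(VAF) of a known hotspot SNV among the original cfDNA molecules of a plasma
sample, and, over time, a patient's minimal-residual-disease trajectory.

The generative model the pipeline assumes (and the simulator implements):

1. A sample contributes `molecules_per_assay` original molecules per assay.
   Each molecule independently carries the tracked mutation with probability
   VAF (Bernoulli), receives a UMI drawn uniformly from 4^L (L = 12 by
   default; collisions are allowed and not prevented), and may acquire
   **early errors** — substitutions on the first copy, per base with
   probability `early_error_rate` — which all descendant reads inherit.
2. The molecule is amplified and sequenced into a family of reads; the
   family size is negative-binomial (mean 8, dispersion 2), truncated at 1.
   These defaults are chosen as a realistic over-dispersed amplification
   profile; the observed distribution of the instrument data they stand in
   for is not published, so they are test conveniences, not fidelity claims.
3. Each read independently acquires **late errors** per base with
   probability `late_error_rate` over the whole read (UMI, primers and
   insert), emulating late PCR cycles and the sequencer.

Reads are single-end, laid out `[UMI][forward primer][insert][reverse
primer read-through]`, truncated at `read_length` (150 by default).
Substitutions only: every in-scope variant is an SNV, so indels and quality
modelling are deliberately absent (constant placeholder qualities).

## Panel representation

A panel file (YAML, 1-based inclusive coordinates; 0-based half-open
internally) defines assays — amplicon and target intervals, primers, a
plus-strand reference insert, a coding frame (offset, strand, first residue
number) — and a hotspot catalogue keyed by (chrom, pos, alt). Loading
validates: unique ids, hotspots inside exactly one assay's target, ref base
consistent with the reference insert, and amplicon sizes within the design
constraints (75–105 bp). Annealing temperatures are carried as inert
metadata; they are not computable from sequence at any useful fidelity.

The bundled NB-ALK instance preserves every published structural number —
seven assays in *ALK* exons 19 and 22–25, amplicon sizes 79–104 bp with both
extremes realised, 351 bp of total target, 20 hotspot SNVs at the canonical
neuroblastoma (F1174, F1245, R1275, I1171, D1091, M1166, Y1278) and
TKI-resistance (T1151, C1156, L1196, L1198, G1202, S1206, G1269, G1286)
codons — but its genomic coordinates and non-hotspot codons are synthetic
placeholders, flagged in the file header. Consequence annotation is
therefore exact for the catalogued codons and structurally correct (standard
genetic code, minus-strand handling) everywhere, without claiming base-level
identity to the genome. The HRAS-Q61 instance uses the published primer pair
(88 bp amplicon) and the real residue 55–69 peptide context around codon 61.

Reads are modelled as starting at the low-coordinate (plus-strand) end of
each amplicon, so extracted inserts are directly in plus-strand orientation;
minus-strand coding (both ALK and HRAS) is resolved at translation time.
This stands in for primer orientation metadata the panel does not model.

## Read processing

Primer-anchored assignment replaces genome alignment: the post-UMI prefix is
compared to each forward primer by Hamming distance and the read is assigned
to the unique assay within 2 mismatches (ties → `rejected_ambiguous`, no
match → `rejected_no_primer`, too-short reads → `rejected_short`). At a late
error rate of 10⁻³/base the chance of > 2 substitutions in a 20–24 bp primer
is below 2×10⁻⁶, so true reads are essentially never lost; at 10⁻² it is
~10⁻³, which the QC tally test checks against the exact binomial tail. The
tally identity `total = assigned + rejected` is asserted on every run.

## Consensus

Families are grouped by exact (assay, UMI) key by default, matching the
grouping rule of the published analysis read literally. A `hamming1` mode
greedily absorbs families into strictly larger ones whose UMI differs by one
base (ties broken lexicographically), acknowledging that UMI sequencing
errors otherwise inflate family counts; it is an option, not the default.

Consensus requires ≥ `min_family_size` reads (default 3, the published
rule). Per position, members covering that position vote; the top base is
called if its frequency is ≥ `majority_threshold`, else `N`. The threshold
default 0.6 is a repository choice, not a published value: it is the largest
round value at which the smallest admissible family (size 3) with one
discordant read (2/3 ≈ 0.67) still resolves. Frequency exactly at the
threshold is called; ties are `N`. Uncovered positions shrink the
denominator; a fully uncovered position is `N`.

Error arithmetic behind the suppression tests: with late error rate p, a
consensus error in a size-3 family needs ≥ 2 reads to draw the *same* wrong
base — leading term 3·3·(p/3)² = p²·1 ≈ 10⁻⁶ at p = 10⁻³, three orders below
the raw rate; larger families are far cleaner. The acceptance test asserts
the conservative 100× floor at ≥ 2000 families. Early errors, by
construction, pass through at the molecule rate — the penetrance test pins
this so the two-tier model cannot silently degrade.

## Calling

VAF, positivity (≥ 1 mutant consensus read) and LOD (100/depth %, rounded
half-up to two decimals for reporting, unrounded retained internally) are
computed over consensus reads. At a representative mean hotspot consensus
depth of 5,180 families the LOD evaluates to 0.02%. Secondary screening reports
every non-reference base at ≥ 1% consensus AF that is nonsynonymous and not
the patient's tracked variant, as `candidate` records — confirmation and
rejection are explicit user actions, mirroring a manual-review step that is
out of scope here. Whether the published 1% screen used consensus or raw
reads is not stated; consensus is used, consistent with the molecule-
counting framing throughout. Tracked hotspots are always an explicit input
(the diagnostic tumor mutation); the caller never auto-selects one.
Zero-depth loci are `non_evaluable`, never negative.

## Monitoring

Samples classify as negative (0 molecules), low_positive (exactly 1),
positive (≥ 2), or non_evaluable. Events over the date-ordered sequence
(non-evaluables skipped): molecular relapse at the first sample of a run
with a positive, or with a low_positive confirmed by any non-negative within
`confirm_window` (default 1) subsequent samples; an unconfirmed low_positive
is an indeterminate event; clearance at the first of ≥ 2 consecutive
negatives after a positive period. The three-tier rule with confirmation is
this package's formalisation of the "interpret single-molecule findings with
caution, repeat sampling decides" recommendation; the published analysis
itself counted any ≥ 1-molecule sample positive, and
`positivity_mode="paper"` / `--strict-paper-positivity` reproduces exactly
that. Calendar arithmetic uses whole days; months are days/30.44 rounded to
one decimal, which makes the 274-day and 91-day fixtures evaluate to the
9.0- and 3.0-month lead times the monitoring tests assert.

## Numerical and determinism choices

All randomness flows from one integer seed through `numpy.random.default_rng`;
time-course sample seeds derive from the master seed via `SeedSequence`
spawning, keeping them below 2³¹. Pipeline outputs are byte-identical across
runs at fixed seed and config. LOD rounding is decimal half-up (not
banker's). VCF output is 4.2, sites-only, 1-based, with counts, VAF percent
and LOD percent in INFO; contig lengths are synthesised from assay extents.

## Problem sizes in the test suite

The statistical suites run at desk scale chosen to make their tail bounds
sharp rather than to mimic production depth: error suppression at 2,500
molecules (≈ 2,100 eligible families), specificity over 50 seeded
mutation-free samples of 500 molecules, VAF recovery on the grid
{0.0005, 0.005, 0.05, 0.5} × 20 seeds at 10⁴ molecules with a pre-registered
acceptance-sampling allowance (≤ 3 misses of 80 at the 0.995 binomial
quantile for a 1% nominal miss rate), and relapse-timing over 20 seeded
rising trajectories at 1,500 molecules.

## Limitations

The simulator omits PCR efficiency bias, polymerase-specific error spectra,
indels, quality scores and duplex (two-strand) schemes; passing tests
demonstrate correctness of the counting and consensus logic under the stated
model, not robustness to artefacts outside it (e.g. strand-biased damage,
primer cross-reactivity on real genomes). Placeholder panel coordinates mean
genomic liftover of the bundled files is meaningless, though any panel file
with real coordinates drops in unchanged. Clinical interpretation (response
criteria, imaging, biomarkers) is out of scope.
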