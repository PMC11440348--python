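panel:
  name: HRAS-Q61
  min_amplicon_bp: 75
  max_amplicon_bp: 105
  notes: Single HRAS codon-61 assay with the published primer pair (88 bp amplicon).
    PLACEHOLDER genomic coordinates; insert encodes HRAS residues 55-69.
assays:
- assay_id: HRAS_e3_55
  chrom: chr11
  amplicon_start: 533861
  amplicon_end: 533948
  target_start: 533882
  target_end: 533926
  forward_primer: GCCCTCCCCGGTGCGCATGTA
  reverse_primer: GGAGACGTGCCTGTTGGACATC
  reference_insert: ATCACGCATAGCAGAATATTCTTCCTGACCAGCAGTATCAAGAAT
  strand: '-'
  coding_frame_offset: 0
  first_codon_number: 55
  covered_mutations:
  - HRAS_Q61L
  annealing_temp_c: 61.4
hotspots:
- hotspot_id: HRAS_Q61L
  gene: HRAS
  chrom: chr11
  pos: 533907
  ref_base: T
  alt_base: A
  protein_change: p.Q61L
  category: tki_resistance
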