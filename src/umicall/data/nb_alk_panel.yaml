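panel:
  name: NB-ALK
  min_amplicon_bp: 75
  max_amplicon_bp: 105
  notes: 'Seven ALK kinase-domain assays (exons 19, 22-25). PLACEHOLDER coordinates
    and flanking sequences: amplicon sizes (79-104 bp), total target length (351 bp)
    and the 20 catalogued hotspot codons are preserved, but genomic positions and
    non-hotspot codons are synthetic.'
assays:
- assay_id: ALK_e19_1085
  chrom: chr2
  amplicon_start: 29213001
  amplicon_end: 29213079
  target_start: 29213021
  target_end: 29213059
  forward_primer: AGGCGTGCATGCGAAGCACA
  reverse_primer: ATGAGTCATAACCCTTAGAC
  reference_insert: CATAGAATCCCAATTATCGTCAGCAGTATAACAACCAAC
  strand: '-'
  coding_frame_offset: 0
  first_codon_number: 1085
  covered_mutations:
  - ALK_D1091N
  annealing_temp_c: 61.7
- assay_id: ALK_e22_1145
  chrom: chr2
  amplicon_start: 29207501
  amplicon_end: 29207586
  target_start: 29207521
  target_end: 29207565
  forward_primer: GATATGCATGAACTTATCTT
  reverse_primer: CGTCCATCAATCTTGCTATAC
  reference_insert: ACGACACCAGCAACAATCAAGAGACGTATTCATATAAGGACACAT
  strand: '-'
  coding_frame_offset: 0
  first_codon_number: 1145
  covered_mutations:
  - ALK_T1151M
  - ALK_C1156Y
  annealing_temp_c: 62.5
- assay_id: ALK_e23_1162
  chrom: chr2
  amplicon_start: 29207001
  amplicon_end: 29207089
  target_start: 29207022
  target_end: 29207069
  forward_primer: GGTGGGGGGCACTGCGATCGA
  reverse_primer: AGTGGCGCGGCCGACCCTAG
  reference_insert: AGGATCACCGAACATTTTGATAGTAACAGCAGTCATTTCATTAACATA
  strand: '-'
  coding_frame_offset: 0
  first_codon_number: 1162
  covered_mutations:
  - ALK_M1166R
  - ALK_I1171N
  - ALK_I1171T
  - ALK_F1174C
  - ALK_F1174L
  - ALK_F1174V
  annealing_temp_c: 60.1
- assay_id: ALK_e23_1192
  chrom: chr2
  amplicon_start: 29206001
  amplicon_end: 29206093
  target_start: 29206022
  target_end: 29206072
  forward_primer: AACTTGAGGCACGATTTGTTA
  reverse_primer: GCGGGTATGCGCGTTTGGCCA
  reference_insert: AGGAGTGGACCAAACCCAGCCCATAAAAACGAGATGCAGAGAACGCATAGA
  strand: '-'
  coding_frame_offset: 0
  first_codon_number: 1192
  covered_mutations:
  - ALK_L1196M
  - ALK_L1198F
  - ALK_G1202R
  - ALK_S1206Y
  annealing_temp_c: 60.9
- assay_id: ALK_e24_1236
  chrom: chr2
  amplicon_start: 29203001
  amplicon_end: 29203097
  target_start: 29203023
  target_end: 29203076
  forward_primer: TAATTTTCCTTTTTGTGAACTT
  reverse_primer: CTTGGGGGGACGATCCACTCC
  reference_insert: AATTTGAACCCATTCAAAATCTTGGAAAGAAGTTTGATTACGACGAACAGGAAA
  strand: '-'
  coding_frame_offset: 0
  first_codon_number: 1236
  covered_mutations:
  - ALK_F1245C
  - ALK_F1245L
  - ALK_F1245V
  annealing_temp_c: 62.9
- assay_id: ALK_e25_1261
  chrom: chr2
  amplicon_start: 29201001
  amplicon_end: 29201100
  target_start: 29201023
  target_end: 29201079
  forward_primer: ACGTCGCCCGCTACCACCGTAA
  reverse_primer: ACACTCTTCTAACGGTTCAGA
  reference_insert: AGCGTAAATACGTCGAGAATAAGCAAAAAAGCCTTGATCTTCCATAAGAGGAAGAAA
  strand: '-'
  coding_frame_offset: 0
  first_codon_number: 1261
  covered_mutations:
  - ALK_G1269A
  - ALK_R1275Q
  - ALK_Y1278S
  annealing_temp_c: 60.5
- assay_id: ALK_e25_1280
  chrom: chr2
  amplicon_start: 29200001
  amplicon_end: 29200104
  target_start: 29200025
  target_end: 29200081
  forward_primer: ACGTCGCGTTGGGTGGGCGCCCGT
  reverse_primer: CCCACTTACCCCGACCGTGAGTA
  reference_insert: AACAATTTGAGAAGAAGGACGAGAAATAGAAGCAACCCCAAAAGGAGGAGCTTTAGC
  strand: '-'
  coding_frame_offset: 0
  first_codon_number: 1280
  covered_mutations:
  - ALK_G1286R
  annealing_temp_c: 60.3
hotspots:
- hotspot_id: ALK_D1091N
  gene: ALK
  chrom: chr2
  pos: 29213041
  ref_base: C
  alt_base: T
  protein_change: p.D1091N
  category: neuroblastoma_hotspot
- hotspot_id: ALK_T1151M
  gene: ALK
  chrom: chr2
  pos: 29207546
  ref_base: G
  alt_base: A
  protein_change: p.T1151M
  category: tki_resistance
- hotspot_id: ALK_C1156Y
  gene: ALK
  chrom: chr2
  pos: 29207531
  ref_base: C
  alt_base: T
  protein_change: p.C1156Y
  category: tki_resistance
- hotspot_id: ALK_M1166R
  gene: ALK
  chrom: chr2
  pos: 29207056
  ref_base: A
  alt_base: C
  protein_change: p.M1166R
  category: neuroblastoma_hotspot
- hotspot_id: ALK_I1171N
  gene: ALK
  chrom: chr2
  pos: 29207041
  ref_base: A
  alt_base: T
  protein_change: p.I1171N
  category: neuroblastoma_hotspot
- hotspot_id: ALK_I1171T
  gene: ALK
  chrom: chr2
  pos: 29207041
  ref_base: A
  alt_base: G
  protein_change: p.I1171T
  category: neuroblastoma_hotspot
- hotspot_id: ALK_F1174C
  gene: ALK
  chrom: chr2
  pos: 29207032
  ref_base: A
  alt_base: C
  protein_change: p.F1174C
  category: neuroblastoma_hotspot
- hotspot_id: ALK_F1174L
  gene: ALK
  chrom: chr2
  pos: 29207031
  ref_base: G
  alt_base: T
  protein_change: p.F1174L
  category: neuroblastoma_hotspot
- hotspot_id: ALK_F1174V
  gene: ALK
  chrom: chr2
  pos: 29207033
  ref_base: A
  alt_base: C
  protein_change: p.F1174V
  category: neuroblastoma_hotspot
- hotspot_id: ALK_L1196M
  gene: ALK
  chrom: chr2
  pos: 29206060
  ref_base: G
  alt_base: T
  protein_change: p.L1196M
  category: tki_resistance
- hotspot_id: ALK_L1198F
  gene: ALK
  chrom: chr2
  pos: 29206054
  ref_base: G
  alt_base: A
  protein_change: p.L1198F
  category: tki_resistance
- hotspot_id: ALK_G1202R
  gene: ALK
  chrom: chr2
  pos: 29206042
  ref_base: C
  alt_base: G
  protein_change: p.G1202R
  category: tki_resistance
- hotspot_id: ALK_S1206Y
  gene: ALK
  chrom: chr2
  pos: 29206029
  ref_base: G
  alt_base: T
  protein_change: p.S1206Y
  category: tki_resistance
- hotspot_id: ALK_F1245C
  gene: ALK
  chrom: chr2
  pos: 29203048
  ref_base: A
  alt_base: C
  protein_change: p.F1245C
  category: neuroblastoma_hotspot
- hotspot_id: ALK_F1245L
  gene: ALK
  chrom: chr2
  pos: 29203047
  ref_base: G
  alt_base: C
  protein_change: p.F1245L
  category: neuroblastoma_hotspot
- hotspot_id: ALK_F1245V
  gene: ALK
  chrom: chr2
  pos: 29203049
  ref_base: A
  alt_base: C
  protein_change: p.F1245V
  category: neuroblastoma_hotspot
- hotspot_id: ALK_G1269A
  gene: ALK
  chrom: chr2
  pos: 29201054
  ref_base: C
  alt_base: G
  protein_change: p.G1269A
  category: tki_resistance
- hotspot_id: ALK_R1275Q
  gene: ALK
  chrom: chr2
  pos: 29201036
  ref_base: C
  alt_base: T
  protein_change: p.R1275Q
  category: neuroblastoma_hotspot
- hotspot_id: ALK_Y1278S
  gene: ALK
  chrom: chr2
  pos: 29201027
  ref_base: T
  alt_base: G
  protein_change: p.Y1278S
  category: neuroblastoma_hotspot
- hotspot_id: ALK_G1286R
  gene: ALK
  chrom: chr2
  pos: 29200063
  ref_base: C
  alt_base: T
  protein_change: p.G1286R
  category: tki_resistance
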