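# Eight-assay multiplexed demo panel (SILAC K+8 / R+10 labelled throughout).
tolerances:
  linear_da: 0.25
  reflector_ppm: 25.0
assays:
  - id: ebp1_total
    accession: 4EBP1_CT
    protein: 4EBP1
    designation: Total, C-terminal
    epitope_start: 109
    epitope_end: 118
    protease: trypsin
    max_missed: 2
    labels: silac
  - id: mtor_ps2448
    accession: MTOR
    protein: mTOR
    designation: p(S2448)
    epitope_start: 2444
    epitope_end: 2450
    required_mods: [phospho@S2448]
    protease: trypsin
    max_missed: 1
    labels: silac
  - id: ctnnb1_ps675
    accession: CTNNB1
    protein: CTNNB1
    designation: p(S675)
    epitope_start: 673
    epitope_end: 680
    required_mods: [phospho@S675]
    protease: trypsin
    max_missed: 1
    labels: silac
  - id: akt1_total
    accession: AKT1
    protein: AKT1
    designation: Total, C-terminal
    epitope_start: 470
    epitope_end: 480
    protease: trypsin
    max_missed: 0
    labels: silac
  - id: ebp1_pt37_46
    accession: 4EBP1_NT
    protein: 4EBP1
    designation: p(T37 or T46)
    epitope_start: 37
    epitope_end: 46
    required_mods: [phospho@T37, phospho@T46]
    any_of: true
    protease: trypsin
    max_missed: 1
    labels: silac
  - id: ebp1_ps65_t70
    accession: 4EBP1_MID
    protein: 4EBP1
    designation: p(S65 or T70)
    epitope_start: 64
    epitope_end: 80
    required_mods: [phospho@S65, phospho@T70]
    any_of: true
    protease: trypsin
    max_missed: 2
    labels: silac
  - id: bad_ps75
    accession: BAD
    protein: BAD
    designation: p(S75)
    epitope_start: 73
    epitope_end: 80
    required_mods: [phospho@S75]
    protease: trypsin
    max_missed: 0
    labels: silac
  - id: rps6_ps235_236
    accession: RPS6
    protein: RPS6
    designation: p(S235 & S236)
    epitope_start: 233
    epitope_end: 249
    required_mods: [phospho@S235, phospho@S236]
    variable_mods: ["phospho:ST"]
    max_extra: 3
    protease: trypsin
    max_missed: 4
    labels: silac
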