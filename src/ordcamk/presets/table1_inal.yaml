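description: CaMKII overexpression on INaL alone; alternating EADs
protocol:
  cycle_length: 2000.0
  n_beats: 500
  ikr_block: 0.85
regulation:
  iso_uM: 0.0
  camk0_overrides:
    INaL: 0.12
expected_eads: alternating
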