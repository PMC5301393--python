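min_identity: 0.3
min_coverage: 0.5
bands:
  dit_classical_max: 270
  dit_classical_p2_max: 350
  dit_evolved_min: 450
  tal_short_max: 450
  tal_long_min: 850
  bppu_extended_min: 401
  tmp_fallback_min: 700
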