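{
  "intercept": -17.515308951433163,
  "w_variant": 17.550773631308495,
  "w_phenotype": 14.169862606702875
}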