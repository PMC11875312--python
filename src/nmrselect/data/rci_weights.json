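{
  "CA": 0.74,
  "C": 0.72,
  "CB": 0.13,
  "N": 0.38,
  "H": 0.15,
  "HA": 0.91
}
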