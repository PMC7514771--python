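{
  "dimension": 2,
  "epsilons": [1.0, 0.125, 0.015625],
  "dx": 0.05,
  "n_angles": 16
}
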