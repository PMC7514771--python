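{
  "example_id": 2,
  "epsilon": 0.015625,
  "n_steps": 1000,
  "seed": 1,
  "method": "two-level",
  "dx": 0.05,
  "n_angles": 16,
  "noise_variance": 1e-4
}
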