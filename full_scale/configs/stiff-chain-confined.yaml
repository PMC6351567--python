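name: stiff-chain-confined
polymer: {kind: semiflexible, N: 25, ring: false, lp: 100.0}
cylinder: {D: 4.0, L: 20.0}
protocol:
  compress_velocity: 1.0e-3
  equil_steps: 100000000
  prod_steps: 200000000
  sample_stride: 10000
  n_replicas: 20
  base_seed: 20260919
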