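name: ring-brush-cg
polymer: {kind: brush, N: 300, Ns: 30, ring: true}
cylinder: {D: 34.0, L: 70.0}
init: {handedness: both}
protocol:
  compress_velocity: 1.0e-3
  equil_steps: 200000000
  prod_steps: 200000000
  sample_stride: 10000
  n_replicas: 20
  base_seed: 20260919
analysis:
  binwidth: 0.1
  coarse_grain: [[average, 2], [average, 3], [skip, 2], [skip, 3]]
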