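name: ring-brush-right
polymer: {kind: brush, N: 200, Ns: 10, ring: true}
cylinder: {D: 18.0, L: 45.0}
init: {handedness: right}
protocol:
  compress_velocity: 1.0e-3
  equil_steps: 200000000
  prod_steps: 200000000
  sample_stride: 10000
  n_replicas: 20
  base_seed: 20260919
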