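name: linear-brush-right
polymer: {kind: brush, N: 200, Ns: 40, ring: false}
cylinder: {D: 30.0, L: 50.0}
init: {handedness: right}
protocol:
  compress_velocity: 1.0e-3
  equil_steps: 200000000
  prod_steps: 200000000
  sample_stride: 10000
  n_replicas: 20
  base_seed: 20260919
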