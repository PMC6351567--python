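# Desk-scale coarse-graining sweep on a small ring bottle brush: the
# backbone writhe distribution is recomputed after replacing blocks of m
# consecutive backbone beads by centroids ("average") or keeping every
# m-th bead ("skip"), emulating finite experimental resolution.
runs:
  - name: ring-brush-cg
    polymer: {kind: brush, N: 60, Ns: 4, ring: true}
    cylinder: {D: 8.0, L: 18.0}
    init: {handedness: both}
    protocol:
      compress_velocity: 5.0e-3
      inflate_steps: 30000
      settle_steps: 10000
      equil_steps: 200000
      prod_steps: 600000
      sample_stride: 500
      n_replicas: 2
      base_seed: 20260919
    analysis:
      binwidth: 0.1
      coarse_grain: [[average, 2], [average, 3], [skip, 2], [skip, 3]]
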