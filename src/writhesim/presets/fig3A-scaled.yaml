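# Desk-scale scan of a linear semiflexible chain (N = 25) in a D = 4a
# cylinder compressed to L = 20a, for a flexible-vs-stiff pair of
# persistence lengths.  Step counts are reduced ~100x from the full
# production schedule; production length is validated against the writhe
# autocorrelation time at analysis time.
runs:
  - name: lp100-L20
    polymer: {kind: semiflexible, N: 25, ring: false, lp: 100.0}
    cylinder: {D: 4.0, L: 20.0}
    protocol: &scaled
      compress_velocity: 5.0e-3
      equil_steps: 400000
      prod_steps: 2000000
      sample_stride: 500
      n_replicas: 8
      base_seed: 20260919
  - name: lp32-L20
    polymer: {kind: semiflexible, N: 25, ring: false, lp: 32.0}
    cylinder: {D: 4.0, L: 20.0}
    protocol: *scaled
  - name: lp100-open
    polymer: {kind: semiflexible, N: 25, ring: false, lp: 100.0}
    cylinder: {D: 4.0, L: open}
    protocol: *scaled
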