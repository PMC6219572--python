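scenario: potential-curve
potential:
  U_a: -0.9
  U_b: -0.9
  d_min: 1.3
  d_max: 8.0
  n_points: 200
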