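# scaled-down annealing run (~1 min); full-scale protocol: n_hot 10000000,
# n_cool 5000000
scenario: anneal
seed: 1
anneal:
  n_proteins: 16
  box: 60.0
  n_hot: 100000
  n_cool: 50000
  table:
    extent: 6.0
    step: 0.5
    n_theta: 6
    resolution: 0.15
    margin: 5.0
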