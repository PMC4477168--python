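init: {A0: 1.5, I0: 1.25, medium_I0: 12.0, noise: 0.01}
params: {}
scenario:
  adhesion: high
  cell_size: 6
  communication: mixed
  lattice: [100, 100]
  mcs_total: 3000
  n_cells: 49
  name: high_mixed
  population: aggregate
  sample_interval: 75
  seed: 7
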