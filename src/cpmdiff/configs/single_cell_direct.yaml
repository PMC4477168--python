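init: {A0: 1.5, I0: 1.25, medium_I0: 12.0, noise: 0.01}
params: {}
scenario:
  adhesion: high
  cell_size: 6
  communication: direct
  lattice: [60, 60]
  mcs_total: 3000
  n_cells: 1
  name: single_cell_direct
  population: single_cell
  sample_interval: 75
  seed: 11
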