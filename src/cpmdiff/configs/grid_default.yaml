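grid:
  name: communication_adhesion_grid
  scenarios:
  - high_direct
  - high_indirect
  - high_mixed
  - single_cell_mixed
  - none_nocomm
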