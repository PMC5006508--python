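# Shuttling scenario: two gal4 copies, two UASx5:gal80 copies
model: reference
dosage:
  q_g: 0.35
  q_r: 2
grid:
  n_nodes: 401
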