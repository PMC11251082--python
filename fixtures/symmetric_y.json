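{
  "kind": "branching",
  "branch_asymmetry": 0.5,
  "n_cells_per_timepoint": 500,
  "n_genes": 300,
  "seed": 0,
  "note": "mirror-image branches: the generative fate of every root cell is 0.5 per branch by construction"
}
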