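# Default screening configuration.
# frozen: "auto" (freeze positions with no receptor site within reach_cutoff)
#         or an explicit list of 1-based positions.
pocket_cutoff: 4.5
reach_cutoff: 8.0
frozen: auto
top_k: 3
per_position_k: {}
forced: {}
enumeration_cap: 1000000
top_n: 10
chi_grid: [-60.0, 60.0, 180.0]
clash_tolerance: 0.4
exclude_residues: [PRO, CYS]
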