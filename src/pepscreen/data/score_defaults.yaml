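# Default score-model parameters (energies in kcal/mol, lengths in Angstrom,
# angles in degrees).  See pepscreen.scoring.ScoreModel for the key schema.
dG0: 1.29
w_hbond: -1.12
w_ionic: -1.98
w_lipo: -0.0406
w_aromatic: -0.17
w_solv: 0.01
w_rot: 0.335
R_ideal: 2.9
dR_tol: 0.2
dR_max: 0.6
dA_tol: 30.0
dA_max: 80.0
temperature: 298.0
probe_radius: 1.4
n_sphere_points: 144
aromatic_cutoff: 5.0
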