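# interaction_type	d_min_angstrom	d_max_angstrom
# Distance windows for type-and-distance contact definitions (heavy atoms).
aromatic_stacking	1.5	3.5
disulfide_bridge	1.8	2.8
hydrogen_bond	2.0	3.9
hydrophobic	2.0	4.5
repulsive	2.0	6.0
salt_bridge	2.0	6.0
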