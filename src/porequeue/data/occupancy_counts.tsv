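strain	total_npcs	npcs_1_particle	npcs_2_particles	total_particles
NOY505	566	25	5	35
OGP103	252	12	2	16
rrn3-8	218	4	0	4
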