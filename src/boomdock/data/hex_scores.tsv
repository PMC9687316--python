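fragment	ligand	score
frag1	LEC2	-670.7
frag1	WUS	-624.5
frag1	LEC1	-722.1
frag1	AGLI5-frag1	-754.3
frag1	AGLI5-frag2	-464.0
frag2	LEC2	-554.0
frag2	WUS	-600.9
frag2	LEC1	-607.1
frag2	AGLI5-frag1	-795.3
frag2	AGLI5-frag2	-506.2
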