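source	complex	dg_kcal_per_mol	kd_M
protein	BBM-frag1:LEC2	-11.2	5.7e-9
protein	BBM-frag1:WUS	-10.6	1.7e-8
protein	BBM-frag1:LEC1	-12.3	8.8e-10
protein	BBM-frag1:AGLI5-frag1	-11.1	7.7e-9
protein	BBM-frag1:AGLI5-frag2	-10.1	4.0e-8
protein	BBM-frag2:LEC2	-8.6	4.8e-7
protein	BBM-frag2:WUS	-9.5	1.0e-7
protein	BBM-frag2:LEC1	-8.7	4.1e-7
protein	BBM-frag2:AGLI5-frag1	-9.7	7.5e-8
protein	BBM-frag2:AGLI5-frag2	-8.5	5.9e-7
peptide	P1:dock16	-7.1	6.0e-6
peptide	P2:dock89	-7.7	2.1e-6
peptide	P2:dock10	-7.2	5.4e-6
peptide	P3:dock49	-8.0	1.5e-6
peptide	P4:dock96	-8.1	1.1e-6
peptide	P5:dock57	-7.7	2.4e-6
peptide	P6:dock2	-6.7	1.2e-5
peptide	P7:dock30	-4.9	2.4e-4
md_cluster	P2:dock10	-6.9	9.1e-6
md_cluster	P4	-6.1	3.5e-5
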