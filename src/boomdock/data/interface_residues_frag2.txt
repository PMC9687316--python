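# Interfacial residue stretches of BBM partner proteins in the
# BBM fragment-2 docked complexes, one partner per [block], one printed
# stretch per line.
[LEC2]
K173, E174, X, K176
V187, X, P189, K190, R191
N228, N229, X, S231, X, M233
[WUS]
R38, W39, X, P41
K82, N83, X, F85, Y86, W87, X, Q89, N90
R94
[LEC1]
Y63, M64, P65
N68
R71, I72
K75, T76
V95
Y98, I99
T103
I118
A120
I123
M127
Y135
L139
F142, I143
Y146
[AGLI5-fragment1]
I8, K9, R10, I11
R17
F21
R24
L28
K31
L35
V43, A44, V45, I46, V47, F48, X, K50
[AGLI5-fragment2]
L97
H101
L104, Q105
Q123, L124, X, H126, A127
T130, V131
R134, K135
L138, L139
Q142
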