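# Interfacial residue stretches of BBM partner proteins in the
# BBM fragment-1 docked complexes, one partner per [block], one printed
# stretch per line.  "X" marks a single missing residue; "R-185" and "R185"
# are equivalent token forms.
[LEC2]
K173, E174, X, K176, N177, S178
L183, X, R-185, X, V-187, X, P-189, K190
W226, X, N228, N229, X, S231, X, M223
I250
[WUS]
R38, W39, T40, P41, X, T43
I46
K50
Y54
W87
N90, H91
R94, E95
[LEC1]
R71, I72, M73, X, K75, T76, X, P78
I91
V95
Y98
I123
M127
G131, F132, D133, N134, Y135, X, D137, P138, L139, X, V141, F142
R145
[AGLI5-fragment1]
I8, K9, R10, I11
R17
F21
R24
L28
L35
E42, V43, A44, V45, I46, V47, F48, X, K50, X, G52
T65
[AGLI5-fragment2]
R132
K135, E136
L139, T140, X, Q142, L143, E144
R147
E150, Q151
E154, L155
E158
R161
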