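# Deleage & Roux (1987) beta-turn conformational parameter
A 0.788
R 0.912
N 1.572
D 1.197
C 0.965
Q 0.997
E 1.149
G 1.860
H 0.970
I 0.240
L 0.670
K 1.302
M 0.436
F 0.624
P 1.453
S 1.316
T 0.739
W 0.546
Y 0.795
V 0.387
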