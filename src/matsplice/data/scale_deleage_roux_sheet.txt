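# Deleage & Roux (1987) beta-sheet conformational parameter
A 0.709
R 0.920
N 0.604
D 0.541
C 1.191
Q 0.840
E 0.567
G 0.657
H 0.863
I 1.799
L 1.261
K 0.721
M 1.210
F 1.393
P 0.354
S 0.928
T 1.221
W 1.306
Y 1.266
V 1.965
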