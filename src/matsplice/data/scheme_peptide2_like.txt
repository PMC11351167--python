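# Peptide 2.0-style four-class residue scheme.
# acidic/basic membership is standard; hydrophobic vs neutral assignment of
# C, G, P, Y follows the hydrophobicity table used for mating-protein
# composition reports.
A hydrophobic
C hydrophobic
D acidic
E acidic
F hydrophobic
G neutral
H basic
I hydrophobic
K basic
L hydrophobic
M hydrophobic
N neutral
P hydrophobic
Q neutral
R basic
S neutral
T neutral
V hydrophobic
W hydrophobic
Y neutral
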