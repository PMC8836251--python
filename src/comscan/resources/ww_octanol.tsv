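# Wimley-White octanol hydrophobicity scale (water -> n-octanol),
# Wimley, Creamer & White (1996) Biochemistry 35:5109-5124.
# Stored sign-flipped relative to the published free energies (kcal/mol) so that
# larger values = more hydrophobic. Asp/Glu/His are the charged-side-chain values.
# residue	value
A	-0.50
R	-1.81
N	-0.85
D	-3.64
C	0.02
E	-3.63
Q	-0.77
G	-1.15
H	-2.33
I	1.12
L	1.25
K	-2.80
M	0.67
F	1.71
P	-0.14
S	-0.46
T	-0.25
W	2.09
Y	0.71
V	0.46
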