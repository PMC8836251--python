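# Side-chain pKa values (Lehninger-style reference set) used for
# Henderson-Hasselbalch net-charge and isoelectric-point calculations.
# Segments are treated as internal windows of a chain: free termini excluded.
# residue	pka	sign
D	3.65	-1
E	4.25	-1
C	8.18	-1
Y	10.07	-1
H	6.00	+1
K	10.53	+1
R	12.48	+1
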