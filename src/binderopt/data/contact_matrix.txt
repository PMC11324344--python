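# binderopt default residue-pair contact potential (arbitrary energy units).
# m[a][b] = -0.05 - max(h_a,0)*max(h_b,0)/20 + 0.5*q_a*q_b, h = Kyte-Doolittle
# hydrophobicity, q = integer side-chain charge (D/E -1, K/R +1, H +0.5).
# Hydrophobic-hydrophobic contacts are favorable (negative), like-charge
# contacts unfavorable, opposite charges favorable. Symmetric by construction.
        A       C       D       E       F       G       H       I       K       L       M       N       P       Q       R       S       T       V       W       Y
A  -0.212  -0.275  -0.050  -0.050  -0.302  -0.050  -0.050  -0.455  -0.050  -0.392  -0.221  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.428  -0.050  -0.050
C  -0.275  -0.362  -0.050  -0.050  -0.400  -0.050  -0.050  -0.613  -0.050  -0.525  -0.287  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.575  -0.050  -0.050
D  -0.050  -0.050   0.450   0.450  -0.050  -0.050  -0.300  -0.050  -0.550  -0.050  -0.050  -0.050  -0.050  -0.050  -0.550  -0.050  -0.050  -0.050  -0.050  -0.050
E  -0.050  -0.050   0.450   0.450  -0.050  -0.050  -0.300  -0.050  -0.550  -0.050  -0.050  -0.050  -0.050  -0.050  -0.550  -0.050  -0.050  -0.050  -0.050  -0.050
F  -0.302  -0.400  -0.050  -0.050  -0.442  -0.050  -0.050  -0.680  -0.050  -0.582  -0.316  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.638  -0.050  -0.050
G  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050
H  -0.050  -0.050  -0.300  -0.300  -0.050  -0.050   0.075  -0.050   0.200  -0.050  -0.050  -0.050  -0.050  -0.050   0.200  -0.050  -0.050  -0.050  -0.050  -0.050
I  -0.455  -0.613  -0.050  -0.050  -0.680  -0.050  -0.050  -1.062  -0.050  -0.905  -0.477  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.995  -0.050  -0.050
K  -0.050  -0.050  -0.550  -0.550  -0.050  -0.050   0.200  -0.050   0.450  -0.050  -0.050  -0.050  -0.050  -0.050   0.450  -0.050  -0.050  -0.050  -0.050  -0.050
L  -0.392  -0.525  -0.050  -0.050  -0.582  -0.050  -0.050  -0.905  -0.050  -0.772  -0.411  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.848  -0.050  -0.050
M  -0.221  -0.287  -0.050  -0.050  -0.316  -0.050  -0.050  -0.477  -0.050  -0.411  -0.230  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.449  -0.050  -0.050
N  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050
P  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050
Q  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050
R  -0.050  -0.050  -0.550  -0.550  -0.050  -0.050   0.200  -0.050   0.450  -0.050  -0.050  -0.050  -0.050  -0.050   0.450  -0.050  -0.050  -0.050  -0.050  -0.050
S  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050
T  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050
V  -0.428  -0.575  -0.050  -0.050  -0.638  -0.050  -0.050  -0.995  -0.050  -0.848  -0.449  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.932  -0.050  -0.050
W  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050
Y  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050  -0.050
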