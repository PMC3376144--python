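# Default residue property table.
# group: 1 = hydrophobic {A,F,G,I,L,M,P,V,W}, 2 = polar {C,N,Q,S,T,Y},
#        3 = positively charged {H,K,R}, 4 = negatively charged {D,E}.
# vdwv: normalized van der Waals volume of the side chain (Fauchere scale),
#       rescaled to the unit interval (glycine 0, tryptophan 1).
residue	group	vdwv
A	1	0.1238
R	3	0.7587
N	2	0.3651
D	4	0.3441
C	2	0.3007
Q	2	0.4889
E	4	0.4678
G	1	0.0000
H	3	0.5767
I	1	0.4950
L	1	0.4950
K	3	0.5903
M	1	0.5483
F	1	0.7290
P	1	0.3366
S	2	0.1980
T	2	0.3218
W	1	1.0000
Y	2	0.8008
V	1	0.3713
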