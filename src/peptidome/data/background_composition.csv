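residue,intracellular_percent,intracellular_sd,nuclear_percent,nuclear_sd
A,7.9,2.9,8.3,5.0
C,1.9,2.4,1.6,1.7
D,5.5,2.0,4.7,2.6
E,7.1,3.2,6.5,3.6
F,3.9,1.8,2.7,1.7
G,7.1,2.6,6.3,2.8
H,2.1,1.4,2.1,1.4
I,5.2,2.0,3.7,2.0
K,6.7,2.8,7.9,6.5
L,8.6,2.4,7.4,3.2
M,2.4,1.3,2.3,1.2
N,4.0,1.8,3.7,2.2
P,5.3,4.0,6.9,3.4
Q,4.4,3.0,4.7,2.8
R,4.9,2.2,8.7,13.5
S,6.6,2.0,8.8,3.2
T,5.3,1.7,5.1,2.1
V,6.8,1.9,5.3,1.8
W,1.2,0.8,0.7,0.7
Y,3.1,1.5,2.4,1.3
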