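residue,human_count,yeast_count
A,866,471
C,3,0
D,645,335
E,690,322
F,376,135
G,787,342
H,137,73
I,502,235
K,696,392
L,900,359
M,164,40
N,309,202
P,560,225
Q,395,172
R,392,131
S,634,304
T,438,241
V,813,377
W,70,9
Y,156,87
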