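residue,g_per_100g
D+N,8.40
E+Q,15.28
S,4.40
H,3.15
G,6.19
T,3.94
R,9.79
A,6.41
Y,2.97
C,0.39
V,7.20
M,1.70
F,5.22
I,4.94
L,8.07
K,6.33
P,5.63
W,0.69
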