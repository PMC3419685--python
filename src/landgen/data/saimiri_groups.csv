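group,n,population
E,12,western
G,13,western
K,28,western
O,10,western
PD,14,western
B,18,eastern
C,18,eastern
H,13,eastern
I,20,eastern
M,22,eastern
P,13,eastern
R,21,eastern
T,11,eastern
V,20,eastern
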