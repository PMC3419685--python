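group1,group2,fst,significant
E,G,0.0502,1
E,K,0.0436,0
E,O,0.0783,1
E,PD,0.0971,1
E,B,0.1621,1
E,C,0.1374,1
E,H,0.1375,1
E,I,0.145,1
E,M,0.1529,1
E,P,0.1781,1
E,R,0.1834,1
E,T,0.1679,1
E,V,0.1247,1
G,K,0.0656,1
G,O,0.0992,1
G,PD,0.1128,1
G,B,0.1299,1
G,C,0.1375,1
G,H,0.1293,1
G,I,0.1233,1
G,M,0.1183,1
G,P,0.1569,1
G,R,0.1515,1
G,T,0.1433,1
G,V,0.1294,1
K,O,0.0705,0
K,PD,0.1095,1
K,B,0.1544,1
K,C,0.138,1
K,H,0.1513,1
K,I,0.1505,1
K,M,0.1353,1
K,P,0.173,1
K,R,0.1747,1
K,T,0.1595,1
K,V,0.1398,1
O,PD,0.0584,1
O,B,0.1222,1
O,C,0.0756,0
O,H,0.1152,1
O,I,0.1013,1
O,M,0.1032,1
O,P,0.1535,1
O,R,0.1436,1
O,T,0.1041,1
O,V,0.07,1
PD,B,0.1345,1
PD,C,0.1207,1
PD,H,0.1262,1
PD,I,0.1171,1
PD,M,0.1385,1
PD,P,0.1919,1
PD,R,0.1909,1
PD,T,0.1368,1
PD,V,0.0997,1
B,C,0.0502,1
B,H,0.0529,1
B,I,0.0438,1
B,M,0.0533,1
B,P,0.0972,1
B,R,0.0659,1
B,T,0.0453,0
B,V,0.0475,1
C,H,0.0629,1
C,I,0.0351,1
C,M,0.0246,0
C,P,0.0647,1
C,R,0.0643,1
C,T,0.0405,1
C,V,0.0364,1
H,I,0.0193,0
H,M,0.061,1
H,P,0.1088,1
H,R,0.0714,1
H,T,0.0428,1
H,V,0.0312,1
I,M,0.0306,1
I,P,0.0888,1
I,R,0.056,1
I,T,0.0163,0
I,V,0.0299,1
M,P,0.0638,0
M,R,0.0671,1
M,T,0.0171,0
M,V,0.0517,1
P,R,0.1123,1
P,T,0.1002,1
P,V,0.0911,1
R,T,0.078,1
R,V,0.0844,1
T,V,0.0424,1
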