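# Diclofenac heavy-atom graph: 19 vertices, 20 edges.
# Vertices 0-5: dichlorophenyl ring; 6,7: Cl; 8: bridging N;
# 9-14: second phenyl ring; 15: CH2; 16: carboxyl C; 17,18: O.
0 1
0 5
0 8
1 2
1 6
2 3
3 4
4 5
5 7
8 9
9 10
9 14
10 11
10 15
11 12
12 13
13 14
15 16
16 17
16 18
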