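compound,printed_ratio
1,0.1
2,1.2
3,0.2
4,0.1
5,6.2
6,0.2
7,<0.1
8,<0.1
9,0.1
10,0.1
11,15.4
12,6.5
13,3.4
14,0.4
15,<0.2
16,4.0
17,0.4
18,0.7
19,0.1
20,0.2
S1RA,547.1
PRE084,>4500
RHM-4,0.00012
PIT,13
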