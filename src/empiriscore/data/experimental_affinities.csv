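compound,target,ki_nM,ci_low_nM,ci_high_nM,censored
1,H3,40.4,17.1,95.9,0
1,sigma1,592,281,1246,0
1,sigma2,64.3,22.3,185,0
2,H3,16.0,8.1,31.7,0
2,sigma1,112,77,164,0
2,sigma2,130,97.8,172,0
3,H3,10.2,3.6,29.0,0
3,sigma1,1409,480,4137,0
3,sigma2,247,117,522,0
4,H3,3.17,2.56,3.91,0
4,sigma1,1531,652,3593,0
4,sigma2,101,49.3,205,0
5,H3,7.70,3.62,16.38,0
5,sigma1,3.64,1.81,7.30,0
5,sigma2,22.4,9.36,53.8,0
6,H3,21.1,3.8,116,0
6,sigma1,638,260,1566,0
6,sigma2,108,46.7,250,0
7,H3,7.86,2.82,21.90,0
7,sigma1,2958,629,13904,0
7,sigma2,75.2,33.1,171,0
8,H3,3.12,0.66,14.60,0
8,sigma1,726,219,2413,0
8,sigma2,29.2,22.2,38.5,0
9,H3,23.0,12.4,42.4,0
9,sigma1,641,340,1209,0
9,sigma2,32.4,19.9,52.6,0
10,H3,5.84,3.35,10.19,0
10,sigma1,1309,373,4599,0
10,sigma2,164,59.2,454,0
11,H3,6.20,1.90,20.40,0
11,sigma1,4.41,2.62,7.40,0
11,sigma2,67.9,41.0,112,0
12,H3,22.0,6.0,83.0,0
12,sigma1,14.8,8.28,26.3,0
12,sigma2,96.2,47.1,196,0
13,H3,37.8,24.0,59.4,0
13,sigma1,51.8,22.5,119,0
13,sigma2,175,67.0,459,0
14,H3,120,63,230,0
14,sigma1,285,123,659,0
14,sigma2,101,40.5,251,0
15,H3,115,26.8,493,0
15,sigma1,10000,,,1
15,sigma2,1795,579,5564,0
16,H3,12.7,4.4,36.9,0
16,sigma1,37.8,20.9,69.6,0
16,sigma2,151,65.9,345,0
17,H3,16.9,8.0,36.0,0
17,sigma1,248,140,439,0
17,sigma2,110,56.4,215,0
18,H3,397,220,715,0
18,sigma1,255,104,626,0
18,sigma2,179,87.9,363,0
19,H3,40.5,12.3,134,0
19,sigma1,408,104,1598,0
19,sigma2,59.7,24.3,147,0
20,H3,38.9,9.5,159,0
20,sigma1,274,138,544,0
20,sigma2,65.9,30.1,144,0
S1RA,H3,10000,,,1
S1RA,sigma1,17.0,,,0
S1RA,sigma2,9300,,,0
PRE084,H3,10000,,,1
PRE084,sigma1,2.2,,,0
PRE084,sigma2,10000,,,1
RHM-4,sigma1,2150,,,0
RHM-4,sigma2,0.26,,,0
PIT,sigma1,0.5,,,0
PIT,sigma2,6.5,,,0
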