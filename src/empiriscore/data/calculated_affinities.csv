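compound,target,dg_kcal,ki_calc_printed
1,sigma1,-8.4,691.27
1,sigma2,-10.0,46.37
1,H3,-9.75,70.73
2,sigma1,-9.5,107.88
2,sigma2,-9.3,151.22
2,H3,-10.06,41.90
3,sigma1,-7.8,1904.01
3,sigma2,-8.8,351.80
3,H3,-10.22,31.98
4,sigma1,-7.9,1608.17
4,sigma2,-9.6,91.12
4,H3,-10.62,16.28
5,sigma1,-11.6,3.11
5,sigma2,-10.6,16.84
5,H3,-11.22,5.91
6,sigma1,-8.5,583.86
6,sigma2,-9.4,127.72
6,H3,-10.95,9.32
7,sigma1,-7.5,3159.97
7,sigma2,-9.8,65.0
7,H3,-11.16,6.54
8,sigma1,-8.4,691.27
8,sigma2,-10.1,39.17
8,H3,-10.9,39.83
9,sigma1,-8.5,583.86
9,sigma2,-10.0,46.37
9,H3,-11.97,1.67
10,sigma1,-8.0,1358.30
10,sigma2,-9.3,151.22
10,H3,-11.66,2.81
11,sigma1,-11.7,2.63
11,sigma2,-9.7,76.96
11,H3,-9.28,156.41
12,sigma1,-10.8,12.01
12,sigma2,-9.5,107.88
12,H3,-8.74,389.31
13,sigma1,-10.0,46.37
13,sigma2,-9.0,250.97
13,H3,-10.21,32.53
14,sigma1,-8.9,297.14
14,sigma2,-9.4,127.72
14,H3,-9.33,143.75
15,sigma1,-6.5,17102.46
15,sigma2,-7.8,1904.01
15,H3,-9.7,76.96
16,sigma1,-10.1,39.17
16,sigma2,-9.1,211.97
16,H3,-8.9,297.14
17,sigma1,-8.8,351.80
17,sigma2,-9.5,107.88
17,H3,-10.09,39.83
18,sigma1,-8.9,297.14
18,sigma2,-8.9,297.14
19,sigma1,-8.5,583.86
19,sigma2,-10.0,46.37
20,sigma1,-9.2,179.04
20,sigma2,-9.9,54.90
S1RA,sigma1,-10.39,24.00
S1RA,sigma2,-6.83,9795.90
PRE084,sigma1,-11.50,3.68
PRE084,sigma2,-6.59,14691.11
RHM-4,sigma1,-7.75,2071.76
RHM-4,sigma2,-11.99,1.61
PIT,sigma1,-12.22,1.09
PIT,sigma2,-11.03,8.14
PIT,H3,-10.71,13.98
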