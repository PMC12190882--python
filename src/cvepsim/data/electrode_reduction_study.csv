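subject,acc_baseline,acc_noretrain,acc_retrained,itr_baseline,itr_noretrain,itr_retrained
1,89.51,95.90,96.00,29.38,15.63,32.41
2,100.00,73.56,100.00,52.77,14.22,35.12
3,100.00,-,-,54.14,-,-
4,89.71,-,98.00,42.40,-,51.72
5,98.00,100.00,98.00,62.63,48.99,68.25
6,100.00,-,-,58.46,-,-
7,90.00,96.08,-,23.31,38.25,-
8,92.60,-,94.83,37.40,-,35.18
9,80.52,-,100.00,28.37,-,47.70
10,96.66,-,-,64.25,-,-
11,100.00,-,-,43.85,-,-
12,100.00,-,-,67.01,-,-
13,96.08,-,-,23.28,-,-
14,98.08,-,-,53.19,-,-
15,100.00,-,-,72.16,-,-
16,91.03,83.53,97.83,46.65,21.58,54.91
17,96.43,-,-,55.81,-,-
18,100.00,-,-,67.11,-,-
19,100.00,-,100.00,63.29,-,50.17
20,98.08,-,96.43,63.14,-,51.78
21,100.00,100.00,97.83,57.30,54.49,37.97
22,100.00,-,100.00,56.59,-,56.02
23,100.00,89.77,98.00,35.98,29.23,41.04
24,92.65,97.83,100.00,30.38,24.20,39.49
25,100.00,100.00,100.00,53.12,48.10,52.70
26,90.18,95.90,96.00,59.43,67.43,77.57
27,100.00,100.00,97.83,74.90,75.51,70.38
28,100.00,100.00,100.00,41.80,32.04,41.04
29,82.36,86.17,94.45,30.59,25.89,31.51
30,100.00,100.00,100.00,50.74,43.19,49.20
31,100.00,-,98.22,35.73,-,23.97
32,100.00,98.00,98.08,46.47,32.79,50.29
33,73.88,95.90,92.73,26.24,58.17,56.03
34,100.00,96.30,100.00,76.10,27.36,58.54
35,97.83,-,-,35.17,-,-
36,88.85,78.38,-,37.04,8.39,-
37,100.00,-,-,69.76,-,-
38,91.00,-,-,48.48,-,-
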