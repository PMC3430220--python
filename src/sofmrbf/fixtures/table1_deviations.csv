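molecule_id,is_test,b3lyp_631gd,b3lyp_sto3g,rbfnn_631gd,rbfnn_sto3g,sofm_rbfnn_631gd,sofm_rbfnn_sto3g
1,0,-17.17,-6.89,-0.12,-1.84,-0.04,-1.18
2,0,-7.88,2.66,0.46,0.12,0.38,0.22
3,0,-9.31,0.85,-0.48,-0.65,-0.38,-0.58
4,0,-9.29,1.27,-0.03,-0.02,-0.01,-0.01
5,0,-9.77,0.14,0.00,-0.01,0.00,0.00
6,1,-9.13,1.04,-0.40,-0.53,-0.34,-0.46
7,0,-9.01,1.11,0.05,-0.01,0.03,0.01
8,0,-12.53,0.28,-0.03,0.00,-0.01,0.00
9,0,-13.13,-3.06,0.00,0.00,0.00,0.00
10,0,-10.9,-0.51,-0.01,-0.01,0.00,0.00
11,0,2.16,12.31,0.07,0.02,0.04,0.01
12,0,2.70,13.23,0.58,0.81,0.55,0.68
13,0,1.72,12.17,-0.34,0.42,-0.34,0.23
14,0,-0.39,10.26,-0.10,0.03,-0.06,0.01
15,0,-1.56,10.1,0.00,0.01,0.00,0.01
16,0,1.69,11.63,0.00,0.01,0.00,0.00
17,0,2.00,12.39,-0.20,0.25,-0.23,0.13
18,0,-8.37,2.73,-0.16,0.05,-0.06,0.03
19,0,-7.30,4.12,-0.28,-0.02,-0.21,-0.01
20,1,-6.93,4.16,-0.22,-0.47,-0.21,-0.41
21,0,-7.68,3.96,0.29,0.01,0.27,0.00
22,0,-10.58,0.56,0.00,0.00,0.00,0.00
23,0,-2.11,8.33,0.01,-0.93,0.06,-0.75
24,0,3.45,12.33,0.35,0.67,0.19,0.45
25,0,-8.07,3.05,-0.53,-0.21,-0.51,-0.18
26,0,-7.90,3.23,0.28,0.18,0.29,0.17
27,1,-8.60,2.58,-0.42,-0.01,-0.38,-0.01
28,0,-8.22,4.07,0.01,0.00,0.00,0.00
29,0,-4.97,6.77,0.00,0.00,0.00,0.00
30,0,1.87,-11.2,0.00,0.02,0.00,0.01
31,1,1.97,-11.27,-0.05,0.00,-0.04,0.00
32,0,0.33,-12.53,-0.01,-0.03,0.00,-0.02
33,1,1.91,-6.79,0.04,-0.03,0.03,-0.03
34,0,0.74,-11.6,0.00,0.00,0.00,0.00
35,0,1.92,-10.83,0.18,0.01,0.15,0.01
36,0,0.62,-14,-0.18,0.00,-0.15,0.00
37,0,1.16,10.52,0.00,0.00,0.00,0.00
38,0,0.76,11.2,0.14,0.12,0.10,0.10
39,0,0.29,11.06,-0.05,-0.09,-0.07,-0.08
40,0,-0.36,10.68,-0.06,-0.39,-0.05,-0.36
41,0,-0.41,11.52,0.00,0.00,0.00,0.00
42,0,-0.04,11.72,0.02,0.40,0.01,0.37
43,0,-0.26,10.28,0.04,-0.05,0.04,-0.03
44,1,-1.14,11.08,1.01,0.95,0.92,0.84
45,0,-0.97,9.89,0.00,0.00,0.00,0.00
46,0,0.03,12.03,0.00,0.00,0.00,0.00
47,0,0.87,10.84,0.02,0.04,0.01,0.02
48,0,-1.67,8.65,0.00,0.00,0.00,0.00
49,0,-3.41,8.59,-0.01,-0.03,0.00,-0.02
50,0,7.47,-0.71,-0.01,0.01,0.01,0.01
51,0,5.60,-0.55,0.00,0.00,0.00,0.00
52,0,7.03,-1.38,0.03,0.00,0.01,0.00
53,0,6.33,-2.14,-0.01,-0.01,-0.01,-0.01
54,0,-2.62,15.71,0.00,0.00,0.00,0.00
55,0,-2.88,15.23,0.12,0.28,0.08,0.25
56,0,-3.88,14.1,-0.12,-0.28,-0.08,-0.25
57,0,-3.89,13.76,0.00,-0.01,0.00,-0.01
58,1,-7.57,9.35,0.00,0.00,0.00,0.00
59,0,-4.88,12.76,1.26,1.19,1.20,1.14
60,0,-7.33,9.84,-1.20,-1.15,-1.16,-1.12
61,0,-6.90,10.9,0.17,0.26,0.20,0.28
62,0,6.39,18.5,0.00,0.00,0.00,0.00
63,0,4.12,17.94,0.00,0.38,0.00,0.35
64,0,-9.96,16.41,0.00,-0.37,0.00,-0.34
65,0,4.19,15.06,0.00,-0.01,0.00,-0.01
66,0,0.55,14.42,0.00,0.00,0.00,0.00
67,0,-3.51,19.3,-0.60,-0.52,-0.47,-0.43
68,0,-2.46,21.15,-0.93,-0.93,-0.85,-0.90
69,0,0.27,22.96,0.51,0.57,0.44,0.54
70,0,0.05,22.7,0.07,0.50,0.04,0.47
71,1,2.43,22.6,0.19,0.18,0.16,0.14
72,0,0.20,19.63,0.01,0.00,0.00,0.00
73,0,-0.88,20.53,-0.16,-0.52,-0.09,-0.48
74,0,7.91,19.5,0.02,0.03,0.01,0.02
75,0,-0.36,22.56,0.38,0.39,0.39,0.40
76,0,2.96,21.38,0.00,0.00,0.00,0.00
77,0,1.69,22.06,0.83,0.53,0.61,0.43
78,0,2.77,21.23,0.00,0.01,0.00,0.01
79,0,2.52,20.27,0.21,0.00,0.13,0.00
80,0,0.84,19.65,0.01,-0.01,0.00,-0.01
81,0,1.17,21.22,0.00,0.00,0.00,0.00
82,0,0.68,20.49,-0.21,0.00,-0.13,0.00
83,1,-2.03,16.73,-0.27,-0.57,-0.26,-0.56
84,1,-0.24,18.15,0.27,0.57,0.26,0.56
85,1,-7.63,2.33,-0.04,0.02,-0.03,0.02
86,0,-4.58,6.59,0.00,0.00,0.00,0.00
87,0,-7.16,5.16,0.48,0.16,0.36,0.12
88,0,-8.00,2.5,0.02,0.10,0.01,0.07
89,0,-3.70,11.26,0.00,0.00,0.00,0.00
90,0,-10.85,0.62,-0.49,-0.26,-0.37,-0.18
91,1,-8.77,5.98,-0.16,-0.17,-0.13,-0.13
92,0,-8.61,1.34,0.00,0.00,0.00,0.00
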