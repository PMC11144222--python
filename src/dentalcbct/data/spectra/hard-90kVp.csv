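# hard-90kVp: tungsten anode 90 kVp, 6.5 mm Al filter
# simplified Kramers + K-line model; mean energy 54.48 keV
energy_keV,weight
10,6.82423198e-20
11,2.11693261e-15
12,2.75209749e-12
13,4.61407430e-10
14,1.96531218e-08
15,3.25490620e-07
16,2.76330442e-06
17,1.44662172e-05
18,5.30107289e-05
19,1.48617100e-04
20,3.39703594e-04
21,6.63105103e-04
22,1.14395352e-03
23,1.78961203e-03
24,2.58903376e-03
25,3.51633122e-03
26,4.53635685e-03
27,5.61036822e-03
28,6.70062483e-03
29,7.77349851e-03
30,8.80116346e-03
31,9.76216411e-03
32,1.06412139e-02
33,1.14285397e-02
34,1.21190127e-02
35,1.27112287e-02
36,1.32066378e-02
37,1.36087762e-02
38,1.39226209e-02
39,1.41540671e-02
40,1.43095197e-02
41,1.43955832e-02
42,1.44188341e-02
43,1.43856596e-02
44,1.43021485e-02
45,1.41740223e-02
46,1.40065973e-02
47,1.38047683e-02
48,1.35730085e-02
49,1.33153806e-02
50,1.30355556e-02
51,1.27368355e-02
52,1.24221789e-02
53,1.20942281e-02
54,1.17553354e-02
55,1.14075893e-02
56,1.10528389e-02
57,1.06927179e-02
58,1.35763605e-01
59,2.40938637e-01
60,9.59367179e-03
61,9.22481003e-03
62,8.85620781e-03
63,8.48860075e-03
64,8.12262626e-03
65,7.75883456e-03
66,7.39769853e-03
67,6.94950173e-02
68,6.68495035e-03
69,3.67582861e-02
70,5.98693050e-03
71,5.64402665e-03
72,5.30542472e-03
73,4.97125649e-03
74,4.64162525e-03
75,4.31660930e-03
76,3.99626497e-03
77,3.68062943e-03
78,3.36972307e-03
79,3.06355170e-03
80,2.76210840e-03
81,2.46537529e-03
82,2.17332495e-03
83,1.88592181e-03
84,1.60312328e-03
85,1.32488081e-03
86,1.05114081e-03
87,7.81845459e-04
88,5.16933414e-04
89,2.56340447e-04
90,0.00000000e+00
91,0.00000000e+00
92,0.00000000e+00
93,0.00000000e+00
94,0.00000000e+00
95,0.00000000e+00
96,0.00000000e+00
97,0.00000000e+00
98,0.00000000e+00
99,0.00000000e+00
100,0.00000000e+00
101,0.00000000e+00
102,0.00000000e+00
103,0.00000000e+00
104,0.00000000e+00
105,0.00000000e+00
106,0.00000000e+00
107,0.00000000e+00
108,0.00000000e+00
109,0.00000000e+00
110,0.00000000e+00
111,0.00000000e+00
112,0.00000000e+00
113,0.00000000e+00
114,0.00000000e+00
115,0.00000000e+00
116,0.00000000e+00
117,0.00000000e+00
118,0.00000000e+00
119,0.00000000e+00
120,0.00000000e+00
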