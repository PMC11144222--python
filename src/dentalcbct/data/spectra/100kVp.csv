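# 100kVp: tungsten anode 100 kVp, 6.5 mm Al filter
# simplified Kramers + K-line model; mean energy 55.92 keV
energy_keV,weight
10,6.01632675e-20
11,1.86893871e-15
12,2.43319544e-12
13,4.08543421e-10
14,1.74277578e-08
15,2.89082133e-07
16,2.45811054e-06
17,1.28894778e-05
18,4.73118840e-05
19,1.32868051e-04
20,3.04240621e-04
21,5.94956867e-04
22,1.02829845e-03
23,1.61175833e-03
24,2.33632083e-03
25,3.17952903e-03
26,4.11039982e-03
27,5.09446739e-03
28,6.09791295e-03
29,7.09039033e-03
30,8.04659212e-03
31,8.94681163e-03
32,9.77681058e-03
33,1.05272709e-02
34,1.11930453e-02
35,1.17723539e-02
36,1.22660178e-02
37,1.26767774e-02
38,1.30087167e-02
39,1.32667951e-02
40,1.34564782e-02
41,1.35834568e-02
42,1.36534377e-02
43,1.36719949e-02
44,1.36444674e-02
45,1.35758927e-02
46,1.34709690e-02
47,1.33340367e-02
48,1.31690754e-02
49,1.29797108e-02
50,1.27692289e-02
51,1.25405944e-02
52,1.22964722e-02
53,1.20392491e-02
54,1.17710571e-02
55,1.14937952e-02
56,1.12091508e-02
57,1.09186196e-02
58,1.27493061e-01
59,2.25529337e-01
60,1.00241765e-02
61,9.72185526e-03
62,9.41886288e-03
63,9.11589214e-03
64,8.81354719e-03
65,8.51235325e-03
66,8.21276536e-03
67,6.61057653e-02
68,7.61992320e-03
69,3.56740653e-02
70,7.03753530e-03
71,6.75085163e-03
72,6.46741595e-03
73,6.18737052e-03
74,5.91083111e-03
75,5.63789005e-03
76,5.36861911e-03
77,5.10307191e-03
78,4.84128619e-03
79,4.58328574e-03
80,4.32908213e-03
81,4.07867632e-03
82,3.83205995e-03
83,3.58921666e-03
84,3.35012308e-03
85,3.11474985e-03
86,2.88306247e-03
87,2.65502201e-03
88,2.43058586e-03
89,2.20970823e-03
90,1.99234075e-03
91,1.77843290e-03
92,1.56793242e-03
93,1.36078567e-03
94,1.15693796e-03
95,9.56333840e-04
96,7.58917303e-04
97,5.64632047e-04
98,3.73421640e-04
99,1.85229692e-04
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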