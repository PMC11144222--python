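# soft-90kVp: tungsten anode 90 kVp, 2.5 mm Al filter
# simplified Kramers + K-line model; mean energy 49.05 keV
energy_keV,weight
10,1.05461772e-08
11,5.27011147e-07
12,7.81333381e-06
13,5.29105436e-05
14,2.12282676e-04
15,5.94050045e-04
16,1.28899923e-03
17,2.32768447e-03
18,3.67187712e-03
19,5.23473295e-03
20,6.91009479e-03
21,8.59652367e-03
22,1.02111649e-02
23,1.16946152e-02
24,1.30099822e-02
25,1.41390993e-02
26,1.50779131e-02
27,1.58321485e-02
28,1.64137244e-02
29,1.68380231e-02
30,1.71219363e-02
31,1.72825450e-02
32,1.73362804e-02
33,1.72984333e-02
34,1.71829063e-02
35,1.70021255e-02
36,1.67670554e-02
37,1.64872752e-02
38,1.61710876e-02
39,1.58256432e-02
40,1.54570676e-02
41,1.50705841e-02
42,1.46706284e-02
43,1.42609530e-02
44,1.38447209e-02
45,1.34245880e-02
46,1.30027758e-02
47,1.25811343e-02
48,1.21611966e-02
49,1.17442259e-02
50,1.13312559e-02
51,1.09231258e-02
52,1.05205093e-02
53,1.01239405e-02
54,9.73383555e-03
55,9.35051056e-03
56,8.97419786e-03
57,8.60505921e-03
58,1.08351478e-01
59,1.90794447e-01
60,7.54147430e-03
61,7.20160321e-03
62,6.86900124e-03
63,6.54359489e-03
64,6.22529189e-03
65,5.91398483e-03
66,5.60955427e-03
67,5.24386911e-02
68,5.02080008e-03
69,2.74858429e-02
70,4.45792333e-03
71,4.18582531e-03
72,3.91975629e-03
73,3.65956714e-03
74,3.40510914e-03
75,3.15623465e-03
76,2.91279756e-03
77,2.67465380e-03
78,2.44166162e-03
79,2.21368191e-03
80,1.99057839e-03
81,1.77221777e-03
82,1.55846989e-03
83,1.34920781e-03
84,1.14430783e-03
85,9.43649565e-04
86,7.47115911e-04
87,5.54593061e-04
88,3.65970473e-04
89,1.81140831e-04
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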