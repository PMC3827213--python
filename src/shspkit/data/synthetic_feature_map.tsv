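column	region	feature	marker
1	n_arm	none	none
2	n_arm	none	none
3	n_arm	none	none
4	n_arm	none	none
5	n_arm	none	none
6	n_arm	none	none
7	n_arm	none	none
8	n_arm	none	none
9	n_arm	none	none
10	n_arm	none	none
11	n_arm	none	none
12	n_arm	none	none
13	n_arm	none	none
14	n_arm	none	none
15	n_arm	none	none
16	n_arm	none	none
17	n_arm	none	none
18	n_arm	none	none
19	n_arm	none	none
20	n_arm	none	none
21	n_arm	none	none
22	n_arm	none	none
23	n_arm	none	none
24	n_arm	none	none
25	n_arm	none	none
26	n_arm	none	none
27	n_arm	none	none
28	n_arm	none	none
29	n_arm	none	none
30	n_arm	none	none
31	n_arm	none	none
32	n_arm	none	none
33	n_arm	none	none
34	n_arm	none	none
35	n_arm	none	none
36	n_arm	none	none
37	n_arm	none	none
38	n_arm	none	none
39	n_arm	none	none
40	n_arm	none	none
41	n_arm	none	none
42	n_arm	none	none
43	n_arm	none	none
44	n_arm	none	none
45	n_arm	none	none
46	n_arm	none	none
47	n_arm	none	none
48	n_arm	none	none
49	n_arm	none	none
50	n_arm	none	none
51	n_arm	none	none
52	n_arm	none	none
53	n_arm	none	none
54	n_arm	none	none
55	n_arm	none	none
56	acd	none	none
57	acd	beta2	none
58	acd	beta2	none
59	acd	beta2	none
60	acd	beta2	none
61	acd	beta2	none
62	acd	beta2	none
63	acd	beta2	none
64	acd	beta2	none
65	acd	none	none
66	acd	none	none
67	acd	beta3	none
68	acd	beta3	none
69	acd	beta3	none
70	acd	beta3	none
71	acd	beta3	none
72	acd	beta3	none
73	acd	beta3	none
74	acd	beta3	none
75	acd	none	none
76	acd	none	none
77	acd	none	none
78	acd	none	none
79	acd	beta4	none
80	acd	beta4	none
81	acd	beta4	none
82	acd	beta4	none
83	acd	beta4	none
84	acd	beta4	none
85	acd	beta4	none
86	acd	beta4	none
87	acd	none	none
88	acd	none	none
89	acd	none	none
90	acd	beta5	none
91	acd	beta5	none
92	acd	beta5	none
93	acd	beta5	none
94	acd	beta5	none
95	acd	beta5	none
96	acd	beta5	none
97	acd	none	none
98	acd	none	none
99	acd	beta6	none
100	acd	beta6	none
101	acd	beta6	none
102	acd	beta6	none
103	acd	beta6	none
104	acd	beta6	none
105	acd	beta6	none
106	acd	none	none
107	acd	none	none
108	acd	none	none
109	acd	L57	none
110	acd	L57	none
111	acd	L57	none
112	acd	L57	none
113	acd	L57	none
114	acd	L57	none
115	acd	L57	none
116	acd	L57	none
117	acd	L57	none
118	acd	L57	none
119	acd	L57	none
120	acd	L57	none
121	acd	L57	none
122	acd	beta7	none
123	acd	beta7	none
124	acd	beta7	beta7_arg
125	acd	beta7	none
126	acd	beta7	none
127	acd	beta7	none
128	acd	beta7	none
129	acd	none	none
130	acd	none	none
131	acd	beta8	none
132	acd	beta8	none
133	acd	beta8	none
134	acd	beta8	none
135	acd	beta8	none
136	acd	beta8	none
137	acd	beta8	none
138	acd	beta8	none
139	acd	none	none
140	acd	none	none
141	acd	beta9	none
142	acd	beta9	none
143	acd	beta9	none
144	acd	beta9	none
145	acd	beta9	none
146	acd	beta9	none
147	acd	none	none
148	c_ext	none	none
149	c_ext	none	none
150	c_ext	none	none
151	c_ext	none	none
152	c_ext	none	none
153	c_ext	none	none
154	c_ext	none	none
155	c_ext	none	none
156	c_ext	none	none
157	c_ext	none	none
158	c_ext	none	none
159	c_ext	none	none
160	c_ext	none	none
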