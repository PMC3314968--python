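# residue	I_ratio
1	0.0817
2	0.0000
3	0.0528
4	0.0399
5	0.0007
6	0.0000
7	0.0000
8	0.0603
9	0.0743
10	0.0143
11	0.0000
12	0.0057
13	0.1191
14	0.0469
15	0.1704
16	0.5743
17	0.5211
18	0.4206
19	0.3234
20	0.4744
21	0.6190
22	0.1616
23	0.4797
24	0.7183
25	0.4631
27	0.3436
28	0.2750
29	0.2389
30	0.4027
31	0.4902
32	0.7061
33	0.6268
34	0.6459
35	0.8386
36	0.9576
37	0.8572
38	0.8747
39	0.8803
40	1.0460
41	0.9466
42	0.9921
43	0.9032
44	1.0068
45	0.9702
46	0.9125
47	1.0160
48	0.9174
49	0.9916
50	0.9837
51	1.0298
52	0.9011
53	0.9071
55	1.0171
56	0.9161
57	1.0106
58	0.9316
59	1.0442
60	0.9336
61	0.9970
62	1.0016
63	1.0182
64	0.9665
65	0.9602
66	0.9889
67	1.0035
68	0.9529
69	0.9817
70	0.9405
71	1.0423
72	0.8924
73	1.0065
74	0.9121
75	1.0051
76	1.0619
77	1.0887
78	1.0500
79	1.0007
80	0.9651
81	0.9764
83	1.0071
84	1.0225
85	0.9347
86	0.9963
87	1.0324
88	0.9840
89	0.8842
90	1.0050
91	0.9518
92	1.0329
93	0.9048
94	0.9685
95	1.0679
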