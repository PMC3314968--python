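# 3 eq: residue	dH_ppm	dN_ppm
1	8.0762	115.3762
2	7.4648	107.1943
3	7.6190	115.7981
4	8.1560	107.8116
5	8.2367	111.9499
6	8.7715	111.5293
7	9.4602	108.2678
8	9.4104	120.4123
9	9.2023	114.1932
10	9.2529	112.1078
11	9.4623	115.8212
12	9.7556	111.7930
13	9.3174	109.2284
14	8.7476	120.4617
15	9.1922	119.8971
16	8.5374	118.7615
17	9.1802	105.9193
18	8.6914	122.8728
19	7.9620	119.6559
20	8.2574	115.6889
21	8.1515	111.1761
22	8.3097	105.9127
23	7.4945	116.4509
24	8.2799	110.2985
25	7.1164	110.1918
27	8.9956	122.2638
28	9.3813	120.2051
29	7.1896	121.9407
30	9.1819	106.2499
31	7.4271	126.6815
32	7.8524	123.9921
33	9.2351	125.9535
34	7.5555	106.7572
35	7.0084	121.3263
36	9.1519	126.1365
37	8.8191	117.1241
38	8.2077	111.5493
39	7.5299	117.9958
40	8.0433	109.0621
41	9.2960	106.9515
42	7.7584	125.3228
43	7.9775	112.8514
44	9.3641	111.4619
45	8.0294	127.1690
46	7.5472	127.7239
47	7.8590	106.6621
48	7.8755	122.6741
49	8.8233	115.0296
50	7.5829	122.5015
51	7.0048	117.6636
52	7.8810	118.2870
53	8.5137	118.1935
55	8.6132	123.0751
56	8.6493	118.0237
57	8.6572	114.8271
58	7.9227	118.6845
59	7.7835	119.1539
60	7.5004	108.1872
61	8.4967	107.3565
62	7.1480	126.4262
63	7.8563	120.6956
64	7.8806	125.5586
65	7.5965	124.1692
66	9.2342	119.2945
67	8.1117	116.2370
68	9.7251	117.7691
69	8.1739	126.6796
70	7.1937	128.5793
71	8.1824	106.9844
72	7.0552	110.3165
73	8.2067	125.8376
74	9.4061	124.7392
75	8.3377	119.0820
76	8.8369	109.3327
77	8.2693	107.3296
78	7.3735	120.4755
79	8.6043	127.3540
80	8.1411	123.8610
81	8.0754	118.1676
82	8.8352	106.9183
83	8.7484	121.5934
84	8.9436	106.1809
85	8.0924	126.5954
86	8.8056	128.6746
87	8.8214	107.6726
88	9.1210	111.1182
89	9.4434	127.1991
90	7.6812	121.6904
91	8.9218	106.0061
92	7.5722	109.7218
93	7.2634	108.7444
94	7.1098	125.4155
95	7.0017	105.1558
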