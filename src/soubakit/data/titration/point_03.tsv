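# 1 eq: residue	dH_ppm	dN_ppm
1	8.0585	115.2895
2	7.4813	107.1111
3	7.6290	115.7611
4	8.1363	107.9209
5	8.2544	111.8800
6	8.7781	111.4605
7	9.4643	108.1571
8	9.3471	119.9652
9	9.1561	113.8354
10	9.2314	112.2488
11	9.4611	115.7197
12	9.6959	111.6236
13	9.2627	108.7245
14	8.6374	120.4135
15	9.1714	119.7867
16	8.5736	118.9315
17	9.1718	105.7956
18	8.6637	122.9337
19	7.9831	119.7481
20	8.2779	115.5743
21	8.1713	111.1711
22	8.3183	105.8491
23	7.5042	116.5420
24	8.2901	110.2975
25	7.0961	110.1782
27	8.9876	122.1590
28	9.3505	120.1700
29	7.1884	121.8076
30	9.1787	106.0960
31	7.4339	126.7991
32	7.8578	123.9786
33	9.2429	125.8807
34	7.5309	106.8107
35	7.0309	121.3731
36	9.0759	125.8481
37	8.8336	117.2044
38	8.2017	111.5215
39	7.5226	118.0444
40	7.9929	108.6207
41	9.2519	106.5544
42	7.6585	125.1713
43	7.9961	112.7856
44	9.3493	111.4545
45	8.0399	127.0937
46	7.5605	127.7173
47	7.8690	106.6509
48	7.8624	122.6313
49	8.8089	115.0699
50	7.6016	122.5268
51	7.0128	117.7700
52	7.9023	118.4013
53	8.5336	118.2080
55	8.6117	123.1033
56	8.6196	118.0498
57	8.6731	114.8701
58	7.9283	118.5842
59	7.7819	119.1487
60	7.4870	108.2414
61	8.4788	107.2884
62	7.1558	126.4074
63	7.8735	120.7467
64	7.7584	125.4331
65	7.5851	124.1404
66	9.2273	119.3266
67	8.1106	116.2194
68	9.6614	117.5329
69	8.1163	126.1904
70	7.1686	128.5800
71	8.2184	107.0065
72	7.0661	110.3065
73	8.2049	125.7812
74	9.3848	124.8317
75	8.3561	119.0181
76	8.8318	109.2737
77	8.2867	107.2635
78	7.3804	120.4450
79	8.6036	127.3950
80	8.1423	123.7719
81	8.0753	118.0973
82	8.8562	107.0449
83	8.7483	121.6501
84	8.9456	106.2084
85	8.1119	126.6286
86	8.8126	128.5462
87	8.8197	107.6878
88	9.1178	111.1826
89	9.4283	127.2974
90	7.6974	121.6794
91	8.9042	105.9381
92	7.5496	109.6405
93	7.2748	108.6770
94	7.1125	125.3075
95	7.0094	105.3308
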