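# apo: residue	dH_ppm	dN_ppm
1	8.0791	115.3251
2	7.4641	107.1409
3	7.6180	115.7342
4	8.1477	107.9151
5	8.2305	111.8232
6	8.7870	111.4866
7	9.4486	108.2009
8	9.1741	118.9026
9	8.9592	112.6937
10	9.2565	112.2212
11	9.4622	115.8828
12	9.4117	111.2133
13	9.0759	107.5710
14	8.3994	119.8269
15	9.1681	119.7813
16	8.5581	118.8753
17	9.1634	105.8348
18	8.6590	122.8666
19	7.9701	119.6739
20	8.2563	115.5749
21	8.1455	111.1215
22	8.3093	105.8604
23	7.4876	116.4278
24	8.2638	110.2782
25	7.1067	110.2660
27	9.0001	122.2233
28	9.3841	120.0431
29	7.1741	121.8871
30	9.1770	106.1553
31	7.4380	126.8520
32	7.8581	123.9823
33	9.2195	125.8767
34	7.5569	106.8295
35	7.0294	121.3126
36	8.8266	125.0699
37	8.8296	117.1569
38	8.2306	111.5430
39	7.5156	118.0294
40	7.8793	107.4782
41	9.1745	105.1925
42	7.4051	124.6552
43	7.9890	112.8092
44	9.3548	111.4431
45	8.0259	127.2111
46	7.5587	127.7150
47	7.8381	106.6550
48	7.8586	122.7177
49	8.8105	114.9839
50	7.5904	122.5347
51	7.0118	117.7256
52	7.8819	118.2815
53	8.5138	118.1362
55	8.6079	122.9893
56	8.6326	117.9542
57	8.6616	114.9365
58	7.9375	118.5907
59	7.7847	119.0565
60	7.5102	108.2035
61	8.4861	107.3323
62	7.1429	126.4475
63	7.8697	120.8429
64	7.5189	125.0601
65	7.5957	124.1038
66	9.2296	119.3563
67	8.0893	116.1571
68	9.4156	116.8810
69	7.9715	124.8919
70	7.1441	128.6894
71	8.1870	106.9851
72	7.0554	110.3504
73	8.1953	125.7466
74	9.3962	124.7795
75	8.3473	119.0929
76	8.8216	109.2153
77	8.2721	107.2733
78	7.3962	120.4640
79	8.6054	127.3206
80	8.1413	123.6682
81	8.0622	118.1139
82	8.8324	106.9643
83	8.7496	121.7025
84	8.9696	106.1930
85	8.1257	126.6869
86	8.8366	128.6782
87	8.8077	107.6048
88	9.1241	111.1769
89	9.4173	127.3609
90	7.6834	121.7077
91	8.8997	105.9528
92	7.5593	109.6899
93	7.2523	108.7745
94	7.1070	125.3857
95	7.0039	105.2431
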