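# 2 eq: residue	dH_ppm	dN_ppm
1	8.0687	115.3121
2	7.4763	107.0971
3	7.6173	115.7270
4	8.1397	107.8930
5	8.2462	111.8102
6	8.7716	111.5757
7	9.4705	108.1222
8	9.3778	120.4005
9	9.1959	114.0883
10	9.2269	112.2416
11	9.4771	115.8115
12	9.7562	111.8355
13	9.2997	109.0249
14	8.7162	120.5104
15	9.1721	119.9147
16	8.5663	118.8643
17	9.1814	105.8394
18	8.6732	122.8990
19	7.9736	119.7048
20	8.2600	115.6736
21	8.1349	111.1884
22	8.3294	105.8286
23	7.4967	116.4723
24	8.2762	110.2992
25	7.1171	110.3457
27	8.9916	122.3040
28	9.3879	120.2201
29	7.1963	121.9054
30	9.1693	106.1147
31	7.4225	126.6248
32	7.8616	124.0408
33	9.2295	125.9840
34	7.5427	106.8335
35	7.0107	121.3923
36	9.1311	126.0598
37	8.8074	117.2117
38	8.2203	111.5601
39	7.5231	118.0207
40	8.0588	109.0092
41	9.2729	106.8169
42	7.7349	125.2247
43	7.9934	112.8406
44	9.3515	111.4666
45	8.0432	127.1189
46	7.5557	127.7239
47	7.8783	106.7391
48	7.8713	122.6872
49	8.8009	115.0568
50	7.5851	122.5606
51	7.0114	117.7202
52	7.8890	118.3769
53	8.5309	118.2672
55	8.5891	123.0241
56	8.6249	118.0951
57	8.6684	114.9139
58	7.9310	118.5814
59	7.7835	119.1436
60	7.4997	108.2464
61	8.4948	107.3287
62	7.1470	126.4288
63	7.8551	120.7848
64	7.8536	125.5401
65	7.5834	124.0894
66	9.2505	119.2540
67	8.1138	116.2360
68	9.7443	117.7557
69	8.1671	126.5502
70	7.1822	128.6313
71	8.2151	106.9924
72	7.0544	110.3021
73	8.1993	125.8113
74	9.4119	124.7745
75	8.3467	119.0756
76	8.8150	109.2667
77	8.2879	107.3067
78	7.3789	120.4904
79	8.6039	127.3753
80	8.1359	123.7901
81	8.0580	118.0958
82	8.8505	107.0678
83	8.7695	121.6166
84	8.9611	106.2989
85	8.1149	126.6864
86	8.8147	128.6530
87	8.7987	107.6755
88	9.1205	111.1215
89	9.4263	127.3299
90	7.6626	121.6755
91	8.9218	105.8223
92	7.5406	109.6737
93	7.2618	108.6983
94	7.0996	125.3634
95	7.0127	105.3463
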