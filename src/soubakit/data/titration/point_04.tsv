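# 1.5 eq: residue	dH_ppm	dN_ppm
1	8.0826	115.3003
2	7.4877	107.1572
3	7.6365	115.7534
4	8.1571	107.8958
5	8.2412	111.8261
6	8.7779	111.5335
7	9.4556	108.1623
8	9.3773	120.2994
9	9.1705	114.0655
10	9.2502	112.1370
11	9.4534	115.8977
12	9.7341	111.7575
13	9.2858	108.8955
14	8.7098	120.4065
15	9.1857	119.7670
16	8.5594	118.7472
17	9.1917	105.8383
18	8.6757	122.8707
19	7.9716	119.5819
20	8.2604	115.7343
21	8.1534	111.1746
22	8.3027	105.8834
23	7.5235	116.4749
24	8.2886	110.3493
25	7.1178	110.2756
27	8.9962	122.1829
28	9.3854	120.1674
29	7.1932	121.9073
30	9.1660	106.0582
31	7.4426	126.7525
32	7.8515	124.0947
33	9.2190	126.0018
34	7.5570	106.7763
35	7.0159	121.3062
36	9.1072	126.0347
37	8.8304	117.1469
38	8.2143	111.6491
39	7.5237	118.0141
40	8.0257	108.8450
41	9.2708	106.7058
42	7.7021	125.2238
43	7.9762	112.9101
44	9.3463	111.5052
45	8.0348	127.1506
46	7.5660	127.7475
47	7.8730	106.6276
48	7.8858	122.6473
49	8.8241	114.9656
50	7.5749	122.5311
51	7.0379	117.7494
52	7.8946	118.3293
53	8.5349	118.3150
55	8.5997	123.1451
56	8.6364	118.0424
57	8.6591	114.9256
58	7.9479	118.6956
59	7.8087	119.1729
60	7.4946	108.2283
61	8.4951	107.2448
62	7.1530	126.4943
63	7.8584	120.8323
64	7.8263	125.4145
65	7.5995	124.0241
66	9.2210	119.1848
67	8.1073	116.2671
68	9.7032	117.6247
69	8.1357	126.5099
70	7.1557	128.7011
71	8.1907	106.9992
72	7.0568	110.2299
73	8.2097	125.8498
74	9.4045	124.8013
75	8.3420	119.0757
76	8.8245	109.2419
77	8.2555	107.2967
78	7.3683	120.5199
79	8.5880	127.3946
80	8.1468	123.8404
81	8.0594	118.1498
82	8.8364	106.9701
83	8.7358	121.6577
84	8.9470	106.2773
85	8.1163	126.6345
86	8.8171	128.5571
87	8.8300	107.6290
88	9.1188	111.1275
89	9.4325	127.2249
90	7.6901	121.6942
91	8.9127	105.9357
92	7.5680	109.7175
93	7.2721	108.7743
94	7.0997	125.4612
95	7.0055	105.2504
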