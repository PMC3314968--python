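# 0.25 eq: residue	dH_ppm	dN_ppm
1	8.0690	115.2999
2	7.4992	107.1697
3	7.6222	115.7852
4	8.1560	107.9664
5	8.2478	111.8862
6	8.7702	111.4925
7	9.4455	108.2284
8	9.2491	119.1423
9	9.0163	113.0191
10	9.2550	112.2512
11	9.4719	115.8886
12	9.5022	111.3203
13	9.1455	107.9811
14	8.4820	119.8952
15	9.1926	119.7600
16	8.5557	118.9205
17	9.1580	105.8160
18	8.6734	122.9697
19	7.9793	119.7478
20	8.2809	115.6138
21	8.1594	111.2992
22	8.3279	105.8991
23	7.5107	116.4522
24	8.2747	110.3575
25	7.1192	110.1079
27	8.9894	122.2279
28	9.3762	120.2710
29	7.1933	121.8438
30	9.1588	106.1131
31	7.4316	126.7452
32	7.8494	124.0459
33	9.2437	125.9489
34	7.5498	106.8069
35	7.0107	121.3420
36	8.9153	125.4185
37	8.8333	117.1785
38	8.2111	111.5114
39	7.5306	117.9685
40	7.9019	107.7796
41	9.1964	105.6098
42	7.4889	124.8005
43	7.9709	112.7798
44	9.3640	111.5126
45	8.0292	127.1933
46	7.5755	127.7051
47	7.8641	106.7841
48	7.8668	122.7594
49	8.8122	115.0137
50	7.5823	122.4746
51	7.0256	117.7988
52	7.8893	118.2456
53	8.5224	118.2313
55	8.6110	123.0546
56	8.6290	117.9474
57	8.6828	114.9305
58	7.9495	118.6822
59	7.7882	119.0832
60	7.4998	108.3090
61	8.4940	107.2098
62	7.1526	126.4004
63	7.8335	120.8028
64	7.5887	125.1484
65	7.5863	123.9636
66	9.2505	119.2239
67	8.1118	116.2147
68	9.5075	117.1064
69	8.0407	125.2697
70	7.1717	128.7127
71	8.1881	106.8863
72	7.0550	110.2875
73	8.2111	125.7779
74	9.3915	124.7805
75	8.3296	119.0540
76	8.8385	109.1854
77	8.2875	107.4464
78	7.3665	120.5545
79	8.5850	127.3622
80	8.1332	123.7909
81	8.0638	118.1845
82	8.8425	107.0032
83	8.7484	121.5920
84	8.9501	106.2414
85	8.1307	126.6900
86	8.8223	128.5637
87	8.8319	107.6152
88	9.1148	111.1876
89	9.4290	127.3124
90	7.6992	121.6577
91	8.9096	105.9357
92	7.5534	109.6873
93	7.2526	108.7910
94	7.0788	125.3756
95	7.0009	105.2406
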