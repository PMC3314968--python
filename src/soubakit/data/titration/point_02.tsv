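# 0.5 eq: residue	dH_ppm	dN_ppm
1	8.0668	115.2752
2	7.4775	107.0627
3	7.6231	115.7062
4	8.1845	107.8432
5	8.2252	111.8777
6	8.7769	111.5291
7	9.4501	108.1597
8	9.2847	119.4801
9	9.0461	113.2894
10	9.2454	112.2760
11	9.4771	115.9467
12	9.5746	111.4904
13	9.1809	108.2093
14	8.5478	120.1393
15	9.1692	119.7864
16	8.5553	118.8519
17	9.1694	105.8761
18	8.6601	122.9348
19	7.9716	119.6041
20	8.2727	115.6249
21	8.1512	111.1916
22	8.3113	105.8629
23	7.5076	116.4249
24	8.2971	110.2723
25	7.1217	110.2638
27	8.9981	122.3015
28	9.3777	120.2474
29	7.1928	121.8865
30	9.1857	106.1349
31	7.4349	126.7718
32	7.8602	123.9051
33	9.2281	126.0083
34	7.5606	106.8129
35	7.0051	121.3718
36	8.9547	125.4925
37	8.8122	117.1626
38	8.2122	111.5337
39	7.5202	117.9929
40	7.9523	108.1264
41	9.2112	105.9730
42	7.5427	124.9066
43	7.9972	112.8606
44	9.3483	111.5057
45	8.0299	127.1203
46	7.5429	127.7365
47	7.8517	106.7248
48	7.8779	122.5762
49	8.8048	114.9693
50	7.5697	122.4750
51	7.0191	117.8291
52	7.8738	118.2938
53	8.5304	118.1310
55	8.5855	123.0567
56	8.6399	117.9212
57	8.6736	114.9515
58	7.9613	118.6556
59	7.7997	119.0456
60	7.4969	108.1942
61	8.4999	107.1554
62	7.1436	126.4197
63	7.8608	120.7175
64	7.6650	125.2588
65	7.6141	124.0449
66	9.2244	119.2147
67	8.1054	116.2252
68	9.5811	117.3259
69	8.0827	125.5980
70	7.1603	128.6779
71	8.1928	106.8983
72	7.0588	110.2782
73	8.2107	125.9143
74	9.4103	124.7753
75	8.3437	119.0103
76	8.8447	109.2347
77	8.2716	107.3412
78	7.3610	120.4690
79	8.5945	127.4662
80	8.1380	123.8077
81	8.0733	118.2257
82	8.8460	107.0389
83	8.7517	121.5924
84	8.9458	106.2416
85	8.1259	126.6703
86	8.8385	128.5392
87	8.8275	107.6695
88	9.1185	111.1143
89	9.4317	127.1877
90	7.6956	121.5799
91	8.9096	105.9976
92	7.5775	109.7082
93	7.2584	108.7302
94	7.0977	125.3700
95	6.9971	105.2045
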