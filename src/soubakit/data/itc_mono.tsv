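# injection	dV_uL	heat_ucal
1	1.000	-3.905631
2	1.000	-3.831060
3	1.000	-3.499688
4	1.000	-3.291393
5	1.000	-3.122511
6	1.000	-2.915757
7	1.000	-2.796769
8	1.000	-2.336463
9	1.000	-2.097732
10	1.000	-1.989450
11	1.000	-1.892087
12	1.000	-1.637285
13	1.000	-1.297590
14	1.000	-1.344558
15	1.000	-1.387107
16	1.000	-1.065769
17	1.000	-1.036177
18	1.000	-0.816999
19	1.000	-0.785209
20	1.000	-0.759641
21	1.000	-0.565809
22	1.000	-0.691112
23	1.000	-0.601886
24	1.000	-0.461919
25	1.000	-0.606075
26	1.000	-0.390359
27	1.000	-0.481325
28	1.000	-0.459555
29	1.000	-0.384844
30	1.000	-0.419024
31	1.000	-0.259367
32	1.000	-0.220329
33	1.000	-0.225388
34	1.000	-0.236784
35	1.000	-0.103716
36	1.000	-0.225444
37	1.000	-0.219647
38	1.000	-0.296183
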