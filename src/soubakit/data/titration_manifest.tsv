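# ligand_uM	path
0.0	titration/point_00.tsv
125.0	titration/point_01.tsv
250.0	titration/point_02.tsv
500.0	titration/point_03.tsv
750.0	titration/point_04.tsv
1000.0	titration/point_05.tsv
1500.0	titration/point_06.tsv
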