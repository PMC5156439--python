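# strain=KF147
fermentation_id	salt_mM	initial_pH	temperature_C	oxygen	day	mu	od_final	heat_10min_pct	oxidative_30min_pct
1	0	6.0	27	high	1	0.87	2.12	0.38	0.045
2	100	6.5	27	high	1	0.77	2.56	1.1	0.10
3	0	6.5	27	low	1	0.79	2.37	0.012	0.10
4	100	6.0	27	low	1	0.87	1.50	0.021	0.12
5	0	6.0	30	low	1	1.16	1.83	0.0077	0.27
6	100	6.5	30	low	1	1.09	2.23	0.12	0.042
7	0	6.5	30	high	2	0.94	2.73	1.7	0.071
8	100	6.0	30	high	2	0.85	1.80	18	0.46
9	0	6.0	35	high	2	1.12	1.99	25	1.7
10	100	6.5	35	high	2	1.09	2.75	53	0.18
11	0	6.5	35	low	2	1.22	2.58	0.79	0.012
12	100	6.0	35	low	2	1.18	1.59	0.93	0.00070
13	100	6.5	30	low	2	1.06	2.21	0.033	0.0023
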