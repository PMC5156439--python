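# strain=SK11
fermentation_id	salt_mM	initial_pH	temperature_C	oxygen	day	mu	od_final	heat_10min_pct	oxidative_30min_pct
1	0	6.0	27	high	1	0.52	1.34	1.2	0.051
2	100	6.5	27	high	1	0.57	1.81	0.36	0.55
3	0	6.5	27	low	1	0.67	2.43	0.63	0.13
4	100	6.0	27	low	1	0.49	1.30	0.35	0.11
5	0	6.0	30	low	1	0.66	1.46	2.5	0.074
6	100	6.5	30	low	1	0.69	2.08	4.0	0.047
7	0	6.5	30	high	2	0.63	1.98	6.8	0.037
8	100	6.0	30	high	2	0.57	1.50	9.4	0.038
9	0	6.0	35	high	2	0.26	1.16	13	58
10	100	6.5	35	high	2	0.25	1.32	6.4	20
11	0	6.5	35	low	2	0.61	1.89	34	0.0084
12	100	6.0	35	low	2	0.50	1.26	7.4	0.010
13	100	6.5	30	low	2	0.74	2.04	3.1	0.036
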