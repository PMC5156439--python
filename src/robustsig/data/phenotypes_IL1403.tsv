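# strain=IL1403
fermentation_id	salt_mM	initial_pH	temperature_C	oxygen	day	mu	od_final	heat_60min_pct	oxidative_30min_pct
1	0	6.0	27	high	1	0.37	1.59	0.23	6.5
2	100	6.5	27	high	1	0.43	2.43	0.75	12
3	0	6.5	27	low	1	0.59	2.42	0.000092	0.0011
4	100	6.0	27	low	1	0.30	1.48	4.5	0.75
5	0	6.0	30	low	1	0.59	1.56	0.000044	0.00046
6	100	6.5	30	low	1	0.73	2.27	0.0075	0.032
7	0	6.5	30	high	2	0.74	2.62	0.0052	0.0065
8	100	6.0	30	high	2	0.39	1.53	3.2	53
9	0	6.0	35	high	2	0.80	2.18	5.3	0.0029
10	100	6.5	35	high	2	0.77	2.42	2.7	1.2
11	0	6.5	35	low	2	1.00	2.90	0.095	0.040
12	100	6.0	35	low	2	0.92	1.77	0.45	0.0042
13	100	6.5	30	low	2	0.76	2.34	0.011	0.0066
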