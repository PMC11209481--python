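number	chrom	start	end	five_ltr	gag	pro	pol	env	three_ltr
1	chr16	19355716	19364289	100.00	99.61	99.89	99.43	99.17	99.66
2	chr2A	82212507	82221098	98.98	99.66	100.00	99.47	99.90	99.15
3	chr8	43516710	43525262	99.66	99.83	98.20	99.40	98.83	99.83
4	chr15	23660410	23668998	99.83	99.22	99.77	99.51	99.46	99.83
5	chr13	66107993	66115813	35.95	98.49	52.25	99.66	99.76	99.66
6	chr5	60565330	60572694	73.42	99.72	99.55	75.25	48.48	98.64
7	chr6	48375302	48381314	98.47	92.91	61.71	6.04	99.85	98.98
8	chrY	2019892	2025806	88.25	91.74	64.86	6.19	99.56	99.15
9	chrY	6151270	6157165	83.82	91.68	65.32	6.04	99.56	99.83
10	chr19	39063080	39068105	98.98	99.22	64.30	6.11	67.35	79.56
11	chrY	1786750	1792226	88.59	91.74	64.86	6.19	99.56	22.83
12	chrY	14791990	14797426	88.59	91.74	64.86	6.19	99.56	16.52
13	chrY	16748108	16753037	0.00	91.35	64.86	6.19	99.56	99.83
14	chr4	168066681	168071528	0.00	92.69	99.77	87.66	0.00	0.00
15	chrY	16516529	16520265	0.00	64.99	64.86	6.19	93.70	0.00
16	chr7	147138951	147141648	0.00	0.00	0.00	16.64	99.12	51.45
17	chr8	76757424	76759791	0.00	0.00	0.00	0.00	86.95	100.00
18	chrY	10590060	10592276	56.90	91.74	7.77	0.00	0.00	0.00
19	chrY	8716313	8718506	0.00	0.00	0.00	6.11	99.32	10.22
20	chrY	10822682	10824473	0.00	0.00	0.00	0.00	58.26	99.66
21	chrY	13999593	14001168	52.81	62.09	0.00	0.00	0.00	0.00
22	chrY	5360268	5361838	52.47	61.92	0.00	0.00	0.00	0.00
23	chrY	13423428	13425003	52.64	62.14	0.00	0.00	0.00	0.00
24	chrY	4753348	4754918	51.96	62.09	0.00	0.00	0.00	0.00
25	chrY	10496235	10498083	0.00	0.00	0.00	0.00	86.41	9.20
26	chrY	9765071	9765511	0.00	0.00	0.00	0.00	21.31	0.00
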