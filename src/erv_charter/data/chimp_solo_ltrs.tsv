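number	chrom	strand	start	end	length	ltr_length_pct	completeness_pct	range	qgap_pct	indel	context
1	chr1	+	137442976	137443751	776	101.19	6.90	(0-10%)	4.81	NA	intergenic
2	chrX	-	88705817	88706830	1014	100.85	6.88	(0-10%)	2.47	NA	intergenic
3	chr2B	+	66792632	66793222	591	100.34	6.84	(0-10%)	0.34	NA	intergenic
4	chr5	-	84066356	84066944	589	100.00	6.82	(0-10%)	0.00	NA	intergenic
5	chr7	-	48429668	48430256	589	100.00	6.82	(0-10%)	0.34	NA	intergenic
6	chr15	+	17411474	17412062	589	100.00	6.82	(0-10%)	0.00	NA	intergenic
7	chr2B	-	80853578	80854165	588	99.83	6.81	(0-10%)	0.00	NA	intergenic
8	chr3	-	161301797	161302385	589	99.83	6.81	(0-10%)	0.00	NA	intron
9	chr4	+	19038454	19039041	588	99.83	6.81	(0-10%)	0.17	NA	intergenic
10	chr8	-	49114425	49115012	588	99.83	6.81	(0-10%)	0.00	NA	intergenic
11	chr10	-	19329882	19330469	588	99.83	6.81	(0-10%)	0.00	NA	intergenic
12	chr14	+	19027337	19028300	964	99.83	6.81	(0-10%)	35.96	deletion;insertion	intron
13	chr2B	+	22085802	22086389	588	99.66	6.80	(0-10%)	0.17	NA	intron
14	chr3	-	81878200	81878786	587	99.66	6.80	(0-10%)	0.17	NA	intergenic
15	chr3	-	84155763	84156349	587	99.66	6.80	(0-10%)	0.17	NA	intergenic
16	chr6	-	79799818	79800406	589	99.66	6.80	(0-10%)	0.34	NA	intergenic
17	chr7	+	14600052	14600637	586	99.49	6.78	(0-10%)	0.34	NA	intron
18	chrY	-	18630426	18631014	589	99.49	6.78	(0-10%)	0.51	NA	intergenic
19	chr2A	-	81498383	81498970	588	99.32	6.77	(0-10%)	0.51	NA	intergenic
20	chrX	+	10991573	10992157	585	99.32	6.77	(0-10%)	0.51	NA	intergenic
21	chr2A	+	78001602	78002185	584	99.15	6.76	(0-10%)	0.68	NA	intergenic
22	chr18	+	10395647	10396231	585	99.15	6.76	(0-10%)	0.68	NA	intergenic
23	chrX	-	138003751	138004333	583	98.98	6.75	(0-10%)	0.00	NA	intergenic
24	chr5	-	38971726	38972307	582	98.64	6.73	(0-10%)	0.00	NA	intergenic
25	chr12	-	50879963	50880545	583	98.47	6.71	(0-10%)	0.69	NA	intergenic
26	chr14	+	28857266	28857843	578	97.96	6.68	(0-10%)	2.04	NA	intergenic
27	chr21	-	979256	979845	590	97.79	6.67	(0-10%)	2.05	NA	intron
28	chr6	+	166662836	166663420	585	97.27	6.63	(0-10%)	2.56	NA	intergenic
29	chr16	-	31333554	31334129	576	96.76	6.60	(0-10%)	2.91	NA	intergenic
30	chr3	+	44753258	44753829	572	96.42	6.58	(0-10%)	3.41	NA	intergenic
31	chr2B	+	27967992	27968572	581	96.25	6.56	(0-10%)	3.58	NA	intron
32	chr7	+	140435975	140436547	573	96.25	6.56	(0-10%)	3.58	NA	intergenic
33	chr2B	-	25439654	25440248	595	96.08	6.55	(0-10%)	2.76	NA	intergenic
34	chr13	-	19353563	19354142	580	95.91	6.54	(0-10%)	4.09	NA	intron
35	chr2B	-	11387988	11388572	585	95.40	6.51	(0-10%)	4.44	NA	intergenic
36	chr3	-	59703426	59704196	771	94.21	6.42	(0-10%)	5.63	NA	intergenic
37	chr11	+	120039148	120039717	570	94.04	6.41	(0-10%)	2.99	NA	intergenic
38	chr1	+	143492646	143493186	541	88.07	6.01	(0-10%)	3.36	NA	intron
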