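number	chrom	strand	start	end	length	completeness_pct	range	qgap_pct	indel	context
1	chr16	-	19355716	19364289	8574	95.90	(90-100%)	1.14	NA	intergenic
2	chr2A	+	82212507	82221098	8592	95.75	(90-100%)	1.32	NA	intergenic
3	chr8	-	43516710	43525262	8553	93.95	(90-100%)	3.39	NA	intergenic
4	chr15	-	23660410	23668998	8589	89.68	(80-90%)	7.89	NA	exonic&intronic
5	chr13	+	66107993	66115813	7821	85.42	(80-90%)	8.35	NA	intergenic
6	chr5	-	60565330	60572694	7365	75.51	(70-80%)	22.56	deletion	intron
7	chr6	+	48375302	48381314	6013	64.13	(60-70%)	35.21	deletion	intergenic
8	chrY	-	2019892	2025806	5915	60.86	(60-70%)	37.99	deletion	intergenic
9	chrY	+	6151270	6157165	5896	60.78	(60-70%)	37.88	deletion	intergenic
10	chr19	+	39063080	39068105	5026	56.83	(50-60%)	41.91	deletion	intergenic
11	chrY	+	1786750	1792226	5477	55.32	(50-60%)	40.62	deletion	intergenic
12	chrY	+	14791990	14797426	5437	55.17	(50-60%)	40.45	deletion	intergenic
13	chrY	-	16748108	16753037	4930	54.55	(50-60%)	39.48	deletion	intergenic
14	chr4	-	168066681	168071528	4848	54.03	(50-60%)	0.96	NA	intergenic
15	chrY	+	16516529	16520265	3737	35.85	(30-40%)	52.96	deletion;insertion	genic&intergenic
16	chr7	-	147138951	147141648	2698	27.43	(20-30%)	11.17	deletion	intergenic
17	chr8	+	76757424	76759791	2368	26.57	(20-30%)	0.48	NA	intron
18	chrY	+	10590060	10592276	2217	24.95	(20-30%)	8.91	NA	intergenic
19	chrY	+	8716313	8718506	2194	22.85	(20-30%)	6.51	NA	intergenic
20	chrY	-	10822682	10824473	1792	19.48	(10-20%)	3.45	NA	intergenic
21	chrY	+	13999593	14001168	1576	17.24	(10-20%)	12.03	deletion	intergenic
22	chrY	+	5360268	5361838	1571	17.18	(10-20%)	12.07	deletion	intergenic
23	chrY	-	13423428	13425003	1576	17.03	(10-20%)	13.10	deletion	intergenic
24	chrY	-	4753348	4754918	1571	16.97	(10-20%)	13.14	deletion	intergenic
25	chrY	-	10496235	10498083	1849	6.83	(0-10%)	67.62	deletion;insertion	intergenic
26	chrY	-	9765071	9765511	441	4.72	(0-10%)	3.10	NA	intergenic
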