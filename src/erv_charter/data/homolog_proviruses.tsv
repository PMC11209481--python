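species	chrom	strand	start	end	pair
chimp	chr2A	+	82212507	82221098	P1
human	chr2	+	82022660	82031279	P1
chimp	chr4	-	168066681	168071528	P2
human	chr4	-	170126345	170133883	P2
chimp	chr6	+	48375302	48381314	P3
human	chr6	+	48873675	48879725	P3
chimp	chr7	-	147138951	147141648	P4
human	chr7	-	150561277	150563994	P4
chimp	chr8	-	43516710	43525262	P5
human	chr8	-	43694016	43702583	P5
chimp	chr8	+	76757424	76759791	P6
human	chr8	+	78652302	78654820	P6
chimp	chr13	+	66107993	66115813	P7
human	chr13	+	84869526	84877320	P7
chimp	chr15	-	23660410	23668998	P8
human	chr15	-	45234477	45243073	P8
chimp	chr16	-	19355716	19364289	P9
human	chr16	-	19393581	19402152	P9
chimp	chr19	+	39063080	39068105	P10
human	chr19	+	40954172	40959178	P10
chimp	chr5	-	60565330	60572694	NA
chimp	chrY	+	1786750	1792226	NA
chimp	chrY	-	2019892	2025806	NA
chimp	chrY	-	4753348	4754918	NA
chimp	chrY	+	5360268	5361838	NA
chimp	chrY	+	6151270	6157165	NA
chimp	chrY	+	8716313	8718506	NA
chimp	chrY	-	9765071	9765511	NA
chimp	chrY	-	10496235	10498083	NA
chimp	chrY	+	10590060	10592276	NA
chimp	chrY	-	10822682	10824473	NA
chimp	chrY	-	13423428	13425003	NA
chimp	chrY	+	13999593	14001168	NA
chimp	chrY	+	14791990	14797426	NA
chimp	chrY	+	16516529	16520265	NA
chimp	chrY	-	16748108	16753037	NA
human	chr1	-	155629408	155632775	NA
human	chr5	-	156660448	156663815	NA
human	chr8	+	145019974	145032719	NA
human	chr10	-	99822511	99825532	NA
human	chr12	+	48509228	48511681	NA
human	chr21	-	18563368	18566735	NA
human	chrY	-	8121821	8126768	NA
human	chrY	+	8996062	9000755	NA
human	chrY	-	9273707	9279611	NA
human	chrY	-	17669948	17671523	NA
human	chrY	-	18622534	18626952	NA
human	chrY	+	21580120	21585551	NA
human	chrY	-	21845475	21850069	NA
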