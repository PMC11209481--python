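species	chrom	strand	start	end	pair
chimp	chr1	+	143492646	143493186	S1
human	chr1	+	168457190	168457732	S1
chimp	chr2A	+	78001602	78002185	S2
human	chr2	+	77807602	77808185	S2
chimp	chr2A	-	81498383	81498970	S3
human	chr2	-	81304430	81305068	S3
chimp	chr3	+	44753258	44753829	S4
human	chr3	+	44534488	44535059	S4
chimp	chr3	-	59703426	59704196	S5
human	chr3	-	59469489	59470030	S5
chimp	chr3	-	81878200	81878786	S6
human	chr3	-	81329902	81330488	S6
chimp	chr3	-	84155763	84156349	S7
human	chr3	-	83618409	83618995	S7
chimp	chr3	-	161301797	161302385	S8
human	chr3	-	163283189	163283777	S8
chimp	chr4	+	19038454	19039041	S9
human	chr4	+	19556097	19556684	S9
chimp	chr5	-	38971726	38972307	S10
human	chr5	+	75859521	75860102	S10
chimp	chr5	-	84066356	84066944	S11
human	chr5	-	105998962	105999549	S11
chimp	chr6	-	79799818	79800406	S12
human	chr6	-	82297755	82298498	S12
chimp	chr6	+	166662836	166663420	S13
human	chr6	+	169084226	169084808	S13
chimp	chr7	+	14600052	14600637	S14
human	chr7	+	14509240	14509827	S14
chimp	chr7	+	140435975	140436547	S15
human	chr7	+	143472173	143472744	S15
chimp	chr8	-	49114425	49115012	S16
human	chr8	-	51178592	51179179	S16
chimp	chr10	-	19329882	19330469	S17
human	chr10	-	18856645	18857233	S17
chimp	chr11	+	120039148	120039717	S18
human	chr11	+	124270705	124271275	S18
chimp	chr12	-	50879963	50880545	S19
human	chr12	+	38144469	38145052	S19
chimp	chr13	-	19353563	19354142	S20
human	chr13	-	38319721	38320300	S20
chimp	chr14	+	19027337	19028300	S21
human	chr14	+	38011040	38012012	S21
chimp	chr14	+	28857266	28857843	S22
human	chr14	+	48011215	48011780	S22
chimp	chr15	+	17411474	17412062	S23
human	chr15	+	39011033	39011621	S23
chimp	chr18	+	10395647	10396231	S24
human	chr18	-	4527618	4528209	S24
chimp	chr21	-	979256	979845	S25
human	chr21	-	14080466	14081052	S25
chimp	chrX	+	10991573	10992157	S26
human	chrX	+	11033746	11034330	S26
chimp	chrX	-	88705817	88706830	S27
human	chrX	-	93273183	93274197	S27
chimp	chrX	-	138003751	138004333	S28
human	chrX	-	142767872	142768454	S28
chimp	chr1	+	137442976	137443751	NA
chimp	chr2B	-	11387988	11388572	NA
chimp	chr2B	+	22085802	22086389	NA
chimp	chr2B	-	25439654	25440248	NA
chimp	chr2B	+	27967992	27968572	NA
chimp	chr2B	+	66792632	66793222	NA
chimp	chr2B	-	80853578	80854165	NA
chimp	chr7	-	48429668	48430256	NA
chimp	chr16	-	31333554	31334129	NA
chimp	chrY	-	18630426	18631014	NA
human	chr1	+	162419359	162419942	NA
human	chr2	+	97964920	97965508	NA
human	chr2	-	125024208	125024792	NA
human	chr2	+	135521883	135522470	NA
human	chr2	-	138860917	138861512	NA
human	chr2	+	171365032	171365617	NA
human	chr2	+	180236847	180237437	NA
human	chr2	-	194256159	194256746	NA
human	chr3	-	154944330	154944911	NA
human	chr4	+	116980222	116980809	NA
human	chr4	+	129080872	129081454	NA
human	chr11	-	62185237	62185824	NA
human	chr12	-	4720007	4720593	NA
human	chr15	-	54594796	54595373	NA
human	chr17	+	52961655	52962071	NA
human	chr18	+	63648105	63648555	NA
human	chr20	-	2809052	2809886	NA
human	chrX	-	144791258	144791846	NA
human	chrY	-	25974734	25975320	NA
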