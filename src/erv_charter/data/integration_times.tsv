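species	chrom	start	end	gag	pro	pol	env	mean_div	t_int	age_internal	d_ltr	t_ltr	age_ltr	pair
chimp	chr2A	82212507	82221098	0.057	0.060	0.063	0.085	0.066	0.33	33.13	0.057	0.14	14.25	H1
human	chr2	82022660	82031279	0.061	0.182	0.204	0.101	0.137	0.69	68.50	0.070	0.18	17.50	H1
chimp	chr4	168066681	168071528	0.051	0.063	NA	NA	0.057	0.29	28.50	NA	NA	NA	H2
human	chr4	170126345	170133883	0.058	0.172	0.214	NA	0.148	0.74	74.00	NA	NA	NA	H2
chimp	chr6	48375302	48381314	0.091	NA	NA	0.078	0.085	0.42	42.25	0.106	0.27	26.00	H3
human	chr6	48873675	48879725	0.063	NA	NA	0.106	0.085	0.42	42.25	0.110	0.28	27.50	H3
chimp	chr7	147138951	147141648	NA	NA	NA	0.235	0.235	1.18	117.50	NA	NA	NA	H4
human	chr7	150561277	150563994	NA	NA	NA	0.197	0.197	0.99	98.50	NA	NA	NA	H4
chimp	chr8	43516710	43525262	0.072	0.076	0.071	0.086	0.076	0.38	38.13	0.103	0.26	25.75	H5
human	chr8	43694016	43702583	0.091	0.177	0.231	0.121	0.155	0.78	77.50	0.107	0.27	26.75	H5
chimp	chr13	66107993	66115813	0.058	NA	0.055	0.070	0.061	0.31	30.50	NA	NA	NA	H6
human	chr13	84869526	84877320	0.054	NA	0.208	0.103	0.122	0.61	60.83	NA	NA	NA	H6
chimp	chr15	23660410	23668998	0.056	0.054	0.046	0.063	0.055	0.27	27.38	0.076	0.19	19.00	H7
human	chr15	45234477	45243073	0.051	0.126	0.206	0.099	0.121	0.60	60.25	0.080	0.20	20.00	H7
chimp	chr16	19355716	19364289	0.053	0.038	0.053	0.063	0.052	0.26	25.88	0.090	0.23	22.00	H8
human	chr16	19393581	19402152	0.059	0.158	0.206	0.089	0.128	0.64	64.00	0.082	0.21	20.50	H8
chimp	chr19	39063080	39068105	0.045	NA	NA	NA	0.045	0.23	22.50	0.109	0.27	27.25	H9
human	chr19	40954172	40959178	0.075	NA	NA	NA	0.075	0.38	37.50	0.097	0.24	24.25	H9
chimp	chr5	60565330	60572694	0.061	0.056	NA	NA	0.059	0.29	29.25	0.089	0.22	22.25	NA
chimp	chrY	1786750	1792226	0.115	NA	NA	0.099	0.107	0.54	53.50	NA	NA	NA	NA
chimp	chrY	2019892	2025806	0.113	NA	NA	0.100	0.107	0.53	53.25	0.144	0.36	36.00	NA
chimp	chrY	6151270	6157165	0.114	NA	NA	0.098	0.106	0.53	53.00	0.144	0.36	36.00	NA
chimp	chrY	8716313	8718506	NA	NA	NA	0.100	0.100	0.50	50.00	NA	NA	NA	NA
chimp	chrY	10590060	10592276	0.114	NA	NA	NA	0.114	0.57	57.00	NA	NA	NA	NA
chimp	chrY	14791990	14797426	0.114	NA	NA	0.099	0.107	0.53	53.25	NA	NA	NA	NA
chimp	chrY	16516529	16520265	NA	NA	NA	0.097	0.097	0.49	48.50	NA	NA	NA	NA
chimp	chrY	16748108	16753037	0.112	NA	NA	0.098	0.105	0.53	52.50	NA	NA	NA	NA
human	chr1	155629408	155632775	NA	0.212	0.156	NA	0.184	0.92	92.00	NA	NA	NA	NA
human	chr5	156660448	156663815	NA	0.215	0.160	NA	0.188	0.94	93.75	NA	NA	NA	NA
human	chr8	145019974	145032719	NA	NA	0.513	0.093	0.303	1.52	151.50	NA	NA	NA	NA
human	chr10	99822511	99825532	NA	NA	0.169	NA	0.169	0.85	84.50	NA	NA	NA	NA
human	chr21	18563368	18566735	NA	0.266	0.190	NA	0.228	1.14	114.00	NA	NA	NA	NA
human	chrY	8121821	8126768	NA	NA	NA	0.125	0.125	0.63	62.50	0.157	0.39	39.25	NA
human	chrY	8996062	9000755	NA	NA	NA	0.133	0.133	0.67	66.50	NA	NA	NA	NA
human	chrY	9273707	9279611	0.114	NA	NA	0.139	0.127	0.63	63.25	0.141	0.35	35.25	NA
human	chrY	18622534	18626952	NA	NA	NA	NA	NA	NA	NA	0.194	0.49	48.50	NA
human	chrY	21580120	21585551	0.105	NA	NA	0.140	0.123	0.61	61.25	NA	NA	NA	NA
human	chrY	21845475	21850069	NA	NA	NA	0.143	0.143	0.72	71.50	NA	NA	NA	NA
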