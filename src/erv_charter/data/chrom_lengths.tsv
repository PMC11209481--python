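assembly	chrom	length
panTro6	chr1	228573443
panTro6	chr2A	113622374
panTro6	chr2B	133141003
panTro6	chr3	202621043
panTro6	chr4	194502333
panTro6	chr5	181907262
panTro6	chr6	175400573
panTro6	chr7	160567423
panTro6	chr8	145638636
panTro6	chr9	138239160
panTro6	chr10	133797422
panTro6	chr11	133037422
panTro6	chr12	134452384
panTro6	chr13	115110184
panTro6	chr14	100883782
panTro6	chr15	99548318
panTro6	chr16	89983829
panTro6	chr17	82630442
panTro6	chr18	76611499
panTro6	chr19	61309027
panTro6	chr20	66533130
panTro6	chr21	33445071
panTro6	chr22	37823149
panTro6	chrX	155397278
panTro6	chrY	26350515
hg38	chr1	248956422
hg38	chr2	242193529
hg38	chr3	198295559
hg38	chr4	190214555
hg38	chr5	181538259
hg38	chr6	170805979
hg38	chr7	159345973
hg38	chr8	145138636
hg38	chr9	138394717
hg38	chr10	133797422
hg38	chr11	135086622
hg38	chr12	133275309
hg38	chr13	114364328
hg38	chr14	107043718
hg38	chr15	101991189
hg38	chr16	90338345
hg38	chr17	83257441
hg38	chr18	80373285
hg38	chr19	58617616
hg38	chr20	64444167
hg38	chr21	46709983
hg38	chr22	50818468
hg38	chrX	156040895
hg38	chrY	57227415
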