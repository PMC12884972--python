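well	assay	locus	primer_f	primer_r	primer_f_mass	primer_r_mass	amplicon_bp	probe	strand	designed_allele	alleles	uep_mass	ep_masses	conc_uM	primer_f_gc	primer_r_gc
1	Ct-2	rpl16	ACGTTGGATGTCGGTAGCTGTTGTTAAACC	ACGTTGGATGATTGAGTTCGTATAGGCAT	9268.1	9002.9	112	ATTTTCGGTTACTCCGC	+	A	C. tubulosa=A	5128.3	A=5455.4	6.92	46.7	41.4
1	Csi-2	rpl16	ACGTTGGATGATGGGTGGAGTAAGCAAAA	ACGTTGGATGTGTTTCATTCCCAAGACTC	9095.0	8858.8	144	GTTTGTATAGGCATTTT	-	C	C. sinensis=C	5222.4	C=5509.6	7.09	44.8	44.8
1	CpITS	ITS	ACGTTGGATGAGATGAACTCTCAACTCTCG	ACGTTGGATGGAATAGATCGCACGATTGGG	9206.1	9351.2	92	CCGCACAACGCACGGCAC	+	T	C. phelypaea=T	5424.5	T=5965.7	7.46	46.7	50
1	CaITS	ITS	ACGTTGGATGTACACGTCACGCATCTTGT	ACGTTGGATGTATCAATAATGCACGGGAGG	8883.8	9335.2	85	CGTCCCTTTGGGGCGATAC	+	C	C. ambigua=C	5796.8	C=6043.9	8.09	48.3	46.7
1	CroITS	ITS	ACGTTGGATGACGTAATCTCTCGTCGCATC	ACGTTGGATGTTCGTTAGCCCACACAACAC	9173.0	9151.0	66	CACACAACACCCACTAAAGC	+	T	C. rosea=T	5993.9	T=6265.1	8.41	50	50
1	CdITS-2	ITS	ACGTTGGATGGTATGGCGTCGAATGGTAG	ACGTTGGATGACTAAACTCAGCGGGTAGTC	9069.0	9271.1	83	CGTCGAATGGTAGACATTGT	+	C	C. deserticola=C	6173.0	C=6420.2	8.69	51.7	50
1	Csa-1	rpl16	ACGTTGGATGGGTGGAAAAATTTGGGTCCG	ACGTTGGATGCCGAACCCATACGTGTTTC	9382.2	8868.8	75	CGTATATTTCCAGATAAACCA	-	A	C. salsa=A	6374.2	A=6645.4	9.00	50	51.7
1	Csa-2	rpl16	ACGTTGGATGTATAGAAACGACAGAAATGAG	ACGTTGGATGCTTTCAAATGCAAAGGATG	9665.4	8980.9	118	CAGGTTTCTTTTTTAGACAAACAA	+	C	C. salsa=C	7326.8	C=7574.0	10.33	38.7	41.4
1	Csi-1	rpl16	ACGTTGGATGCTCTTCAAGCACTTGAACCC	ACGTTGGATGTCCACCACGACGTGTATTTC	9142.0	9173.0	88	CCACGACGTGTATTTCGTGTCATTGC	-	G	C. sinensis=G	7929.1	G=8176.3	11.09	50	50
2	Cd-2	rpl16	ACGTTGGATGGTCGCTTGGATCACATCTA	ACGTTGGATGGGCTGGTCTTACTGTAACTG	8923.9	9284.1	120	GGAAATATACGGACCCA	+	A	C. deserticola=A	5213.4	A=5540.5	7.08	48.3	50
2	Cd-1	rpl16	ACGTTGGATGCTATGCCTATACGAACTCAA	ACGTTGGATGCCAAGACTAATTTCTGTCG	9190.1	8907.9	77	ACTCAATTTATTATTTCT	-	A	C. deserticola=A	5414.6	A=5685.8	7.44	43.3	44.8
2	CriITS	ITS	ACGTTGGATGTCGCGAACATGTATAATCAC	ACGTTGGATGCTTCACGAGTAATCCTTGGC	9230.1	9213.0	141	GGATGCGACGAGAGATTA	+	A	C. ridgewayana=A	5613.7	A=5940.8	7.78	43.3	50
2	CdITS-1	ITS	ACGTTGGATGCCTCCCGTGCATTATTGATG	ACGTTGGATGGAGTTGAGAGTTCAACCACC	9204.0	9271.1	87	TCGCCGCAGGATCCCATTT	+	T	C. deserticola=T	5740.7	T=6011.9	8.00	50	50
2	Ct-1	rpl16	ACGTTGGATGACGTGGATCACATCTAGACA	ACGTTGGATGCCATTTCGTGTCATTGCTCG	9255.1	9195.0	54	CATCTAGACAAATTGAAGC	-	A	C. tubulosa=A	5805.8	A=6077.0	8.11	46.7	50
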