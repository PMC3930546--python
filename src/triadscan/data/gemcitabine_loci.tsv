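top_snp	lowest_r	lowest_p	nearby_gene	chr	position	maf	region	n_snps_in_locus
rs10513968	-0.382	1.04E-06	DOK6	18	65434121	0.445	Intron	9
rs7719624	-0.370	4.22E-06	TGFBI	5	135405465	0.448	Intron	28
rs2274870	0.362	4.33E-06	NIPSNAP3A	9	106555035	0.371	Coding	7
rs316838	-0.345	1.21E-05	PLD5	1	240387283	0.093	Intron	12
rs2638094	-0.339	1.72E-05	ZNF215	11	6938064	0.679	Flanking_3UTR	5
rs2290344	0.339	1.75E-05	PIGB	15	53407088	0.253	Coding	9
rs3129890	0.332	2.67E-05	HLA-DRA	6	32522251	0.340	Flanking_3UTR	23
rs2928445	-0.331	2.76E-05	IPMK	10	58816782	0.267	Flanking_3UTR	23
rs4392391	-0.318	5.78E-05	C3orf23	3	44247970	0.419	Downstream	15
rs12522395	0.318	6.58E-05	MASS1	5	90246274	0.215	Intron	4
rs13171512	-0.313	7.857E-05	PIK3R1	5	68000787	0.462	Flanking_3UTR	4
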