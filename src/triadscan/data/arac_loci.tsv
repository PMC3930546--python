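top_snp	lowest_r	lowest_p	nearby_gene	chr	position	maf	region	n_snps_in_locus
rs10495285	0.393	4.13E-07	URB2	1	227871618	0.171	Downstream	2
rs1450679	0.389	5.20E-07	SMC2L1	9	106066633	0.098	Flanking_3UTR	8
rs6128386	0.375	1.38E-06	LOC149773	20	56626955	0.466	Upstream	4
rs2172820	-0.373	1.63E-06	TUSC3	8	15370039	0.256	Flanking_5UTR	13
rs2857891	-0.372	1.75E-06	ZNF215	11	6919533	0.101	Intron	6
rs9512755	-0.361	3.67E-06	LNX2	13	27056229	0.055	Flanking_5UTR	4
rs888468	-0.356	5.08E-06	FGF6	12	4403640	0.184	Flanking_3UTR	5
rs2653165	-0.347	9.28E-06	PLD5	1	240432905	0.207	Intron	7
rs11215416	-0.346	9.57E-06	IGSF4	11	114582537	0.147	Intron	7
rs10060641	0.335	1.90E-05	MASS1	5	90249006	0.216	Intron	7
rs5989586	0.336	1.94E-05	HDHD1A	23	6757306	0.457	Flanking_3UTR	8
rs216465	-0.330	2.76E-05	GOSR1	17	25880801	0.494	Flanking_3UTR	12
rs856548	-0.326	3.29E-05	TNS3	7	46730993	0.296	Flanking_3UTR	8
rs6689258	0.325	3.40E-05	GPR137B	1	234362702	0.267	Flanking_5UTR	2
rs3794794	-0.325	3.61E-05	CPD	17	25744867	0.477	Intron	10
rs7192	0.322	4.10E-05	HLA-DRA	6	32519624	0.371	Coding	11
rs4572738	0.322	4.45E-05	CAST1	3	55799452	0.321	Intron	8
rs1433446	0.319	5.05E-05	TMEM83	15	85351874	0.109	Flanking_5UTR	5
rs300962	0.320	5.47E-05	LOC51334	5	119909842	0.269	Intron	15
rs6441911	0.315	6.20E-05	RIS1	3	45322523	0.055	Flanking_5UTR	6
rs1159388	0.314	6.61E-05	DCAMKL1	13	35544706	0.172	Intron	11
rs718979	0.313	6.82E-05	UBE3A	15	23325370	0.394	Flanking_5UTR	6
rs1955412	0.309	8.74E-05	FLRT2	14	85082547	0.21	Intron	11
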