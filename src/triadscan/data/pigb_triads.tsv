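snp_id	snp_chr	snp_pos	region	maf	probeset_id	gene_symbol	probeset_chr	r_snp_ic50	p_snp_ic50	r_snp_expr	p_snp_expr	r_expr_ic50	p_expr_ic50
rs2290344	15	53407088	Coding	0.253	205452_at	PIGB	15	0.339	1.75E-05	-0.340	1.06E-08	-0.212	5.31E-03
rs2290344	15	53407088	Coding	0.253	242760_x_at	PIGB	15	0.339	1.75E-05	-0.301	4.81E-07	-0.294	8.98E-05
rs4774760	15	53376504	5-upstream	0.416	205452_at	PIGB	15	0.326	3.63E-05	-0.283	2.48E-06	-0.212	5.31E-03
rs4774760	15	53376504	5-upstream	0.416	242760_x_at	PIGB	15	0.326	3.63E-05	-0.240	6.85E-05	-0.294	8.98E-05
rs8024695	15	53426597	Intron	0.285	205452_at	PIGB	15	0.321	5.00E-05	-0.326	4.60E-08	-0.212	5.31E-03
rs8024695	15	53426597	Intron	0.285	242760_x_at	PIGB	15	0.321	5.00E-05	-0.282	2.56E-06	-0.294	8.98E-05
rs12050587	15	53414820	Intron	0.450	205452_at	PIGB	15	0.305	1.23E-04	-0.246	4.54E-05	-0.212	5.31E-03
rs28668016	15	53398725	5-UTR	0.365	205452_at	PIGB	15	0.304	1.31E-04	-0.346	5.97E-09	-0.212	5.31E-03
rs28668016	15	53398725	5-UTR	0.365	242760_x_at	PIGB	15	0.304	1.31E-04	-0.274	5.28E-06	-0.294	8.98E-05
rs11636687	15	53392444	5-upstream	0.421	205452_at	PIGB	15	0.302	1.53E-04	-0.287	2.22E-06	-0.212	5.31E-03
rs7174876	15	53406853	Intron	0.423	205452_at	PIGB	15	0.284	4.06E-04	-0.261	1.64E-05	-0.212	5.31E-03
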