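exposure	snp_id	gene	chrom	effect_allele	eaf	beta	se	pvalue
Carbohydrate	rs10163409	FTO	16	A	0.69	0.19	0.05	2.2 × 10^−4
Carbohydrate	rs197273	TANK	2	A	0.48	0.23	0.04	9.6 × 10^−8
Carbohydrate	rs838145	IZUMO1	19	G	0.46	0.25	0.04	1.68 × 10^−8
Protein	rs1421085	FTO	16	C	0.42	0.09	0.023	4.80 × 10^−7
Protein	rs838133	FGF21	19	G	0.55	0.11	0.02	7.9 × 10^−9
Fat	rs838145	IZUMO1	19	A	0.54	0.21	0.04	1.57 × 10^−9
Smoking (number)	rs1051730	CHRNA3	15	A	0.35	1.021	0.056	2.75 × 10^−73
Smoking (number)	rs1329650	LOC100188947	10	G	0.72	0.367	0.059	5.67 × 10^−10
Smoking (number)	rs3733829	CYP2A6	19	G	0.36	0.333	0.058	1.04 × 10^−8
Smoking initiation	rs6265	BDNF	11	C	0.79	0.061	0.011	1.84 × 10^−8
Smoking cessation	rs3025343	DBH	9	G	0.84	0.121	0.022	3.56 × 10^−8
Sleep	rs1191685	PAX8	2	C	0.37	2.87	0.47	1.06 × 10^−9
Sleep	rs2394403	CBWD	6	C	0.8	3.07	0.56	4.39 × 10^−8
Sleep	rs4248149	CBWD	6	T	0.8	3.08	0.56	3.95 × 10^−8
Sleep	rs4587207	CBWD	6	A	0.8	3.14	0.56	2.02 × 10^−8
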