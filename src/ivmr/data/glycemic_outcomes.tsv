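exposure	snp_id	effect_allele	outcome	beta	se	pvalue
Carbohydrate	rs10163409	A	T2D	0.020	0.018	0.370
Carbohydrate	rs10163409	A	HOMA-IR	0.006	0.005	0.201
Carbohydrate	rs10163409	A	HOMA-B	0.002	0.004	0.580
Carbohydrate	rs10163409	A	fasting insulin	0.004	0.005	0.327
Carbohydrate	rs10163409	A	fasting glucose	0.004	0.004	0.309
Carbohydrate	rs10163409	A	HbA1c	-0.008	0.004	0.041
Carbohydrate	rs10163409	A	2hGLU	0.015	0.022	0.495
Carbohydrate	rs197273	A	T2D	0.000	0.015	0.970
Carbohydrate	rs197273	A	HOMA-IR	-0.002	0.004	0.606
Carbohydrate	rs197273	A	HOMA-B	-0.005	0.003	0.159
Carbohydrate	rs197273	A	fasting insulin	-0.002	0.004	0.667
Carbohydrate	rs197273	A	fasting glucose	0.003	0.004	0.500
Carbohydrate	rs197273	A	HbA1c	0.002	0.004	0.609
Carbohydrate	rs197273	A	2hGLU	0.021	0.019	0.280
Carbohydrate	rs838145	G	T2D	0.020	0.017	0.230
Carbohydrate	rs838145	G	HOMA-IR	-0.002	0.004	0.716
Carbohydrate	rs838145	G	HOMA-B	0.003	0.003	0.405
Carbohydrate	rs838145	G	fasting insulin	-0.001	0.004	0.879
Carbohydrate	rs838145	G	fasting glucose	0.001	0.004	0.720
Carbohydrate	rs838145	G	HbA1c	0.005	0.004	0.165
Carbohydrate	rs838145	G	2hGLU	-0.013	0.020	0.498
Protein	rs1421085	C	T2D	0.104	0.014	4.40 × 10^−11
Protein	rs1421085	C	HOMA-IR	0.016	0.004	9.55 × 10^−5
Protein	rs1421085	C	HOMA-B	0.008	0.003	0.020
Protein	rs1421085	C	fasting insulin	-0.015	0.004	7.48 × 10^−5
Protein	rs1421085	C	fasting glucose	0.007	0.004	0.053
Protein	rs1421085	C	HbA1c	0.008	0.004	0.028
Protein	rs1421085	C	2hGLU	-0.001	0.019	0.981
Protein	rs838133	G	T2D	0.010	0.018	0.720
Protein	rs838133	G	HOMA-IR	0.002	0.005	0.626
Protein	rs838133	G	HOMA-B	0.002	0.004	0.546
Protein	rs838133	G	fasting insulin	0.001	0.004	0.904
Protein	rs838133	G	fasting glucose	0.001	0.004	0.805
Protein	rs838133	G	HbA1c	-0.006	0.004	0.153
Protein	rs838133	G	2hGLU	0.013	0.021	0.534
Fat	rs838145	A	T2D	-0.020	0.017	0.230
Fat	rs838145	A	HOMA-IR	0.002	0.004	0.716
Fat	rs838145	A	HOMA-B	0.003	0.003	0.405
Fat	rs838145	A	fasting insulin	0.001	0.004	0.879
Fat	rs838145	A	fasting glucose	-0.001	0.004	0.720
Fat	rs838145	A	HbA1c	-0.005	0.004	0.165
Fat	rs838145	A	2hGLU	0.013	0.020	0.498
Sleep	rs1191685	C	T2D	-0.010	0.015	0.370
Sleep	rs1191685	C	HOMA-IR	0.002	0.005	0.655
Sleep	rs1191685	C	HOMA-B	0.004	0.004	0.270
Sleep	rs1191685	C	fasting insulin	0.002	0.005	0.701
Sleep	rs1191685	C	fasting glucose	-0.005	0.004	0.225
Sleep	rs1191685	C	HbA1c	-0.006	0.004	0.119
Sleep	rs1191685	C	2hGLU	0.028	0.021	0.184
Sleep	rs2394403	C	T2D	0.030	0.015	0.094
Sleep	rs2394403	C	HOMA-IR	0.002	0.005	0.685
Sleep	rs2394403	C	HOMA-B	0.003	0.005	0.464
Sleep	rs2394403	C	fasting insulin	0.001	0.005	0.840
Sleep	rs2394403	C	fasting glucose	-0.002	0.005	0.676
Sleep	rs2394403	C	HbA1c	-0.003	0.005	0.482
Sleep	rs2394403	C	2hGLU	0.002	0.026	0.943
Sleep	rs4248149	T	T2D	0.030	0.015	0.076
Sleep	rs4248149	T	HOMA-IR	0.002	0.006	0.783
Sleep	rs4248149	T	HOMA-B	0.002	0.005	0.655
Sleep	rs4248149	T	fasting insulin	0.000	0.005	0.934
Sleep	rs4248149	T	fasting glucose	-0.001	0.005	0.821
Sleep	rs4248149	T	HbA1c	-0.002	0.005	0.747
Sleep	rs4248149	T	2hGLU	-0.005	0.027	0.849
Sleep	rs4587207	A	T2D	0.010	0.015	0.670
Sleep	rs4587207	A	HOMA-IR	0.001	0.005	0.798
Sleep	rs4587207	A	HOMA-B	0.003	0.005	0.456
Sleep	rs4587207	A	fasting insulin	0.000	0.005	0.937
Sleep	rs4587207	A	fasting glucose	-0.003	0.005	0.552
Sleep	rs4587207	A	HbA1c	-0.003	0.005	0.506
Sleep	rs4587207	A	2hGLU	-0.002	0.026	0.940
Smoking (number)	rs1051730	A	T2D	-0.030	0.017	0.035
Smoking (number)	rs1051730	A	HOMA-IR	0.003	0.004	0.459
Smoking (number)	rs1051730	A	HOMA-B	-0.002	0.004	0.657
Smoking (number)	rs1051730	A	fasting insulin	0.002	0.004	0.663
Smoking (number)	rs1051730	A	fasting glucose	0.003	0.004	0.430
Smoking (number)	rs1051730	A	HbA1c	0.004	0.004	0.281
Smoking (number)	rs1051730	A	2hGLU	0.001	0.020	0.951
Smoking (number)	rs1329650	G	T2D	0.010	0.013	0.290
Smoking (number)	rs1329650	G	HOMA-IR	-0.008	0.004	0.055
Smoking (number)	rs1329650	G	HOMA-B	-0.004	0.004	0.300
Smoking (number)	rs1329650	G	fasting insulin	-0.006	0.004	0.169
Smoking (number)	rs1329650	G	fasting glucose	-0.005	0.004	0.192
Smoking (number)	rs1329650	G	HbA1c	-0.005	0.004	0.226
Smoking (number)	rs1329650	G	2hGLU	0.007	0.020	0.742
Smoking (number)	rs3733829	G	T2D	0.010	0.015	0.410
Smoking (number)	rs3733829	G	HOMA-IR	0.002	0.004	0.713
Smoking (number)	rs3733829	G	HOMA-B	-0.002	0.004	0.595
Smoking (number)	rs3733829	G	fasting insulin	-0.001	0.004	0.752
Smoking (number)	rs3733829	G	fasting glucose	0.003	0.004	0.418
Smoking (number)	rs3733829	G	HbA1c	0.003	0.004	0.362
Smoking (number)	rs3733829	G	2hGLU	-0.016	0.020	0.444
Smoking initiation	rs6265	C	T2D	0.010	0.015	0.500
Smoking initiation	rs6265	C	HOMA-IR	0.005	0.005	0.346
Smoking initiation	rs6265	C	HOMA-B	0.003	0.004	0.494
Smoking initiation	rs6265	C	fasting insulin	0.004	0.005	0.392
Smoking initiation	rs6265	C	fasting glucose	0.001	0.005	0.793
Smoking initiation	rs6265	C	HbA1c	0.009	0.004	0.042
Smoking initiation	rs6265	C	2hGLU	-0.033	0.024	0.166
Smoking cessation	rs3025343	G	T2D	0.068	0.038	0.099
Smoking cessation	rs3025343	G	HOMA-IR	0.020	0.008	0.010
Smoking cessation	rs3025343	G	HOMA-B	0.008	0.007	0.233
Smoking cessation	rs3025343	G	fasting insulin	0.016	0.008	0.032
Smoking cessation	rs3025343	G	fasting glucose	0.016	0.007	0.029
Smoking cessation	rs3025343	G	HbA1c	0.011	0.007	0.093
Smoking cessation	rs3025343	G	2hGLU	0.038	0.039	0.330
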