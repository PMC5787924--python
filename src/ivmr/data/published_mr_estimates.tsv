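exposure	outcome	beta	se	p
Carbohydrate	T2D	0.051	0.045	0.262
Carbohydrate	HOMA-IR	0.000	0.011	0.981
Carbohydrate	HOMA-B	0.000	0.009	0.990
Carbohydrate	fasting insulin	0.001	0.010	0.957
Carbohydrate	fasting glucose	0.011	0.010	0.282
Carbohydrate	HbA1c	0.003	0.010	0.745
Carbohydrate	2hGLU	0.029	0.052	0.582
Protein	T2D	0.806	0.260	0.002
Protein	HOMA-IR	0.067	0.035	0.046
Protein	HOMA-B	0.045	0.027	0.092
Protein	fasting insulin	-0.047	0.033	0.157
Protein	fasting glucose	0.038	0.029	0.203
Protein	HbA1c	0.049	0.041	0.231
Protein	2hGLU	0.062	0.141	0.662
Fat	T2D	-0.079	0.070	0.261
Fat	HOMA-IR	0.007	0.020	0.722
Fat	HOMA-B	0.014	0.016	0.400
Fat	fasting insulin	0.003	0.019	0.881
Fat	fasting glucose	-0.007	0.018	0.713
Fat	HbA1c	-0.020	0.015	0.175
Fat	2hGLU	0.062	0.095	0.519
Sleep	T2D	0.005	0.003	0.058
Sleep	HOMA-IR	0.001	0.001	0.487
Sleep	HOMA-B	0.001	0.001	0.128
Sleep	fasting insulin	0.000	0.001	0.713
Sleep	fasting glucose	-0.001	0.001	0.222
Sleep	HbA1c	-0.001	0.001	0.106
Sleep	2hGLU	0.003	0.004	0.534
Smoking cessation	T2D	0.559	0.328	0.090
Smoking cessation	HOMA-IR	0.165	0.072	0.021
Smoking cessation	HOMA-B	0.064	0.055	0.247
Smoking cessation	fasting insulin	0.132	0.066	0.047
Smoking cessation	fasting glucose	0.132	0.064	0.039
Smoking cessation	HbA1c	0.093	0.058	0.107
Smoking cessation	2hGLU	0.314	0.326	0.337
Smoking initiation	T2D	0.249	0.380	0.515
Smoking initiation	HOMA-IR	0.079	0.085	0.353
Smoking initiation	HOMA-B	0.048	0.071	0.503
Smoking initiation	fasting insulin	0.069	0.081	0.397
Smoking initiation	fasting glucose	0.020	0.077	0.799
Smoking initiation	HbA1c	0.141	0.073	0.055
Smoking initiation	2hGLU	-0.541	0.403	0.182
Smoking (number)	T2D	-0.013	0.014	0.357
Smoking (number)	HOMA-IR	0.001	0.004	0.835
Smoking (number)	HOMA-B	-0.003	0.003	0.367
Smoking (number)	fasting insulin	0.000	0.004	0.914
Smoking (number)	fasting glucose	0.002	0.004	0.575
Smoking (number)	HbA1c	0.003	0.003	0.379
Smoking (number)	2hGLU	-0.001	0.018	0.944
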