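group	pair_no	gene_a	gene_b	ka	ks	ka_ks	date_mya	duplicate_type
Ia	1	GmIQD1	GmIQD24	0.0474	0.0802	0.5914	6.57	S
Ia	2	GmIQD16	GmIQD27	0.045	0.195	0.228	15.99	S
Ia	3	GmIQD22	GmIQD29	0.029	0.108	0.267	8.83	S
Ia	4	GmIQD49	GmIQD52	0.041	0.106	0.388	8.66	S
Ia	5	GmIQD15	GmIQD59	0.041	0.158	0.258	12.96	S
Ia	6	GmIQD31	GmIQD57	0.029	0.147	0.194	12.03	S
Ia	7	GmIQD37	GmIQD66	0.030	0.116	0.260	9.48	S
Ib	8	GmIQD4	GmIQD34	0.044	0.124	0.356	10.18	S
Ib	9	GmIQD38	GmIQD65	0.054	0.111	0.485	9.07	S
Ib	10	GmIQD8	GmIQD64	0.039	0.134	0.293	11.00	S
Ic	11	GmIQD23	GmIQD55	0.017	0.086	0.193	7.08	S
Id	12	GmIQD13	GmIQD19	0.057	0.164	0.346	13.47	S
IIa	13	GmIQD11	GmIQD39	0.043	0.093	0.460	7.60	O
IIa	14	GmIQD33	GmIQD40	0.022	0.094	0.238	7.70	S
IIb	15	GmIQD6	GmIQD26	0.022	0.091	0.245	7.49	S
IIIa	16	GmIQD10	GmIQD18	0.030	0.152	0.197	12.43	S
IIIa	17	GmIQD50	GmIQD61	0.031	0.162	0.189	13.30	S
IIIa	18	GmIQD21	GmIQD28	0.041	0.125	0.325	10.22	S
IIIa	19	GmIQD48	GmIQD53	0.029	0.111	0.262	9.08	S
IIIa	20	GmIQD25	GmIQD44	0.052	0.157	0.335	12.84	S
IIIa	21	GmIQD45	GmIQD54	0.034	0.105	0.325	8.57	S
IIIa	22	GmIQD42	GmIQD46	0.058	0.219	0.263	17.94	S
IIIa	23	GmIQD41	GmIQD47	0.037	0.095	0.387	7.78	S
IIIb	24	GmIQD35	GmIQD43	0.033	0.114	0.293	9.34	S
IIIb	25	GmIQD7	GmIQD63	0.024	0.093	0.253	7.61	S
IIIb	26	GmIQD36	GmIQD67	0.045	0.127	0.349	10.43	S
IV	27	GmIQD12	GmIQD20	0.054	0.134	0.400	10.99	S
IV	28	GmIQD14	GmIQD58	0.035	0.118	0.297	9.66	S
IV	29	GmIQD2	GmIQD5	0.059	0.109	0.537	8.93	S
IV	30	GmIQD30	GmIQD62	0.067	0.151	0.443	12.35	S
IV	31	GmIQD9	GmIQD17	0.028	0.078	0.363	6.39	S
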