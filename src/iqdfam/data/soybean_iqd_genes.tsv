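name	gene_id	chromosome	start	end	orf_bp	length_aa	pi	mw_kd	exons
GmIQD1	Glyma01g01030	1	681417	683646	1263	420	10.3	46.6	3
GmIQD2	Glyma01g05100	1	4750065	4755456	1692	563	9.7	61.7	6
GmIQD3	Glyma01g42620	1	53843322	53846963	1191	396	10.4	44.4	4
GmIQD4	Glyma02g00710	2	502944	506146	1254	417	9.6	46.8	3
GmIQD5	Glyma02g02370	2	1778568	1785636	1692	563	9.8	61.7	6
GmIQD6	Glyma02g15590	2	14083370	14089609	1608	535	10.8	60.1	5
GmIQD7	Glyma03g33560	3	41092523	41096935	1434	477	10.0	53.3	5
GmIQD8	Glyma03g40630	3	46330165	46332185	1125	374	10.5	42.4	3
GmIQD9	Glyma04g02830	4	2030287	2036251	2715	904	5.4	99.2	6
GmIQD10	Glyma04g05520	4	4187757	4190317	1353	450	10.5	49.9	5
GmIQD11	Glyma04g23760	4	27192306	27195532	1353	450	9.8	50.8	5
GmIQD12	Glyma04g34150	4	40144241	40151603	1752	583	9.4	64.6	6
GmIQD13	Glyma04g41380	4	47220698	47225472	1392	463	9.6	51.7	4
GmIQD14	Glyma05g01240	5	785189	792757	1761	586	9.7	64.9	6
GmIQD15	Glyma05g03450	5	2638386	2641896	1338	445	10.0	48.9	4
GmIQD16	Glyma05g35920	5	39871246	39873985	1128	375	10.0	41.4	4
GmIQD17	Glyma06g02841	6	1950849	1956820	2532	843	5.7	92.8	6
GmIQD18	Glyma06g05530	6	3957759	3960421	1353	450	10.7	49.8	5
GmIQD19	Glyma06g13470	6	10606168	10611219	1341	446	9.7	50.1	4
GmIQD20	Glyma06g20341	6	16752231	16759304	1755	584	9.5	64.9	6
GmIQD21	Glyma07g01040	7	607467	610485	1302	433	10.0	47.9	5
GmIQD22	Glyma07g01760	7	1164144	1167157	1191	396	10.2	44.6	3
GmIQD23	Glyma07g05680	7	4335391	4339373	1641	546	10.3	61.2	5
GmIQD24	Glyma07g14910	7	14801071	14803234	1398	465	10.0	51.8	3
GmIQD25	Glyma07g32531	7	37416802	37421879	873	290	10.6	32.8	5
GmIQD26	Glyma07g32860	7	37753882	37759623	1602	533	10.9	59.7	5
GmIQD27	Glyma08g03710	8	2630927	2633769	1311	436	10.2	48.2	3
GmIQD28	Glyma08g20430	8	15453660	15456579	1266	421	10.4	46.4	5
GmIQD29	Glyma08g21430	8	16271106	16273575	1209	402	10.3	45.2	3
GmIQD30	Glyma08g40880	8	40742659	40748073	1644	547	9.8	60.6	6
GmIQD31	Glyma09g26630	9	33163730	33169453	1449	482	10.0	53.3	4
GmIQD32	Glyma09g30780	9	37552192	37557238	1305	434	10.1	48.0	6
GmIQD33	Glyma09g35920	9	41794962	41798738	1407	468	9.9	52.6	5
GmIQD34	Glyma10g00630	10	386683	389158	1272	423	9.5	47.5	3
GmIQD35	Glyma10g05720	10	4477640	4481520	1425	474	10.0	52.8	5
GmIQD36	Glyma10g35721	10	43974896	43978361	1452	483	10.6	53.0	5
GmIQD37	Glyma10g38310	10	46118444	46123432	1395	464	10.4	51.0	4
GmIQD38	Glyma10g39030	10	46764292	46767407	1410	469	9.7	52.0	4
GmIQD39	Glyma11g20880	11	17714458	17717939	1374	457	10.0	51.7	5
GmIQD40	Glyma12g01410	12	842971	846738	1383	460	10.0	51.8	5
GmIQD41	Glyma12g31610	12	35181013	35188577	1269	422	9.9	46.5	6
GmIQD42	Glyma12g35711	12	38833825	38837834	885	294	9.8	34.2	5
GmIQD43	Glyma13g20070	13	23539750	23543840	1413	470	10.1	52.3	5
GmIQD44	Glyma13g24070	13	27399608	27404534	774	257	10.5	29.3	4
GmIQD45	Glyma13g30590	13	33154582	33158861	900	299	10.4	33.6	5
GmIQD46	Glyma13g34700	13	36237460	36241896	1173	390	9.8	45.5	6
GmIQD47	Glyma13g38800	13	39521853	39528595	1278	425	9.9	47.1	6
GmIQD48	Glyma13g42440	13	42441870	42445047	1239	412	10.3	45.8	5
GmIQD49	Glyma13g43031	13	42796469	42804226	1143	380	10.2	43.4	3
GmIQD50	Glyma14g11050	14	9335703	9339095	1254	417	10.3	47.3	5
GmIQD51	Glyma14g25860	14	31470493	31475301	1377	458	10.0	51.3	4
GmIQD52	Glyma15g02370	15	1595640	1598698	1137	378	10.2	43.3	3
GmIQD53	Glyma15g02940	15	2051157	2053854	1251	416	10.3	45.9	5
GmIQD54	Glyma15g08660	15	6125483	6129362	927	308	10.3	34.7	5
GmIQD55	Glyma16g02240	16	1759053	1762330	1653	550	10.2	61.6	5
GmIQD56	Glyma16g22935	16	26564269	26565120	426	141	11.1	16.3	2
GmIQD57	Glyma16g32161	16	35337880	35343544	1434	477	10.0	52.8	4
GmIQD58	Glyma17g10660	17	8002515	8009332	1767	588	9.5	65.0	6
GmIQD59	Glyma17g14000	17	10763173	10767584	1344	447	10.0	48.9	4
GmIQD60	Glyma17g23770	17	23932487	23938307	1386	461	10.4	50.7	5
GmIQD61	Glyma17g34520	17	38500561	38503843	1242	413	10.4	46.7	5
GmIQD62	Glyma18g16130	18	16440695	16446996	1644	547	9.7	60.3	6
GmIQD63	Glyma19g36270	19	43610551	43615073	1434	477	10.0	53.3	5
GmIQD64	Glyma19g43300	19	48995941	48998264	1113	370	10.6	42.2	3
GmIQD65	Glyma20g28800	20	37708013	37709907	1434	477	9.8	52.7	3
GmIQD66	Glyma20g29550	20	38392614	38397440	1371	456	10.5	50.3	4
GmIQD67	Glyma20g31810	20	40423269	40426995	1470	489	10.4	53.7	5
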