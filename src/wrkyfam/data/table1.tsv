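name	gene_id	group	chromosome	cds_bp	protein_aa	mw_kda	pi	localization
KoWRKY1	GWHGACBH000028	III	1	1140	379	41.67	5.61	Nucleus
KoWRKY2	GWHGACBH000887	IIe	3	966	321	34.70	9.19	Nucleus
KoWRKY3	GWHGACBH001429	I	3	1782	593	65.33	6.42	Nucleus
KoWRKY4	GWHGACBH001604	IIc	4	690	229	26.08	9.28	Nucleus
KoWRKY5	GWHGACBH002143	I	4	1830	609	66.94	6.41	Nucleus
KoWRKY6	GWHGACBH002442	IIc	14	909	302	32.75	5.67	Nucleus
KoWRKY7	GWHGACBH002459	I	14	1539	512	55.56	8.48	Nucleus
KoWRKY8	GWHGACBH002730	I	7	2124	707	76.97	5.72	Nucleus
KoWRKY9	GWHGACBH002784	I	7	1821	606	65.46	8.03	Nucleus
KoWRKY10	GWHGACBH002876	IIc	7	609	202	23.29	7.63	Nucleus
KoWRKY11	GWHGACBH003097	IIe	7	1050	349	38.14	9.57	Nucleus
KoWRKY12	GWHGACBH004007	IIe	10	1053	350	37.84	9.51	Nucleus
KoWRKY13	GWHGACBH004049	I	10	1197	398	43.53	7.97	Nucleus
KoWRKY14	GWHGACBH004052	IIa	10	1056	351	39.03	8.85	Nucleus
KoWRKY15	GWHGACBH004948	IIe	5	978	325	37.09	10.06	Nucleus
KoWRKY16	GWHGACBH005530	III	5	930	309	34.98	7.70	Nucleus
KoWRKY17	GWHGACBH005786	I	5	1395	464	50.98	8.68	Nucleus
KoWRKY18	GWHGACBH005967	I	5	963	320	35.81	5.40	Nucleus
KoWRKY19	GWHGACBH006079	IIc	5	894	297	32.95	5.05	Nucleus
KoWRKY20	GWHGACBH006691	I	13	1425	474	51.38	8.43	Nucleus
KoWRKY21	GWHGACBH006702	IIc	13	927	308	33.18	6.46	Nucleus
KoWRKY22	GWHGACBH007120	IIe	2	510	169	18.80	8.39	Nucleus
KoWRKY23	GWHGACBH007304	IIc	2	351	116	12.99	9.35	Nucleus
KoWRKY24	GWHGACBH007535	IIc	2	1035	344	38.06	7.13	Nucleus
KoWRKY25	GWHGACBH008207	I	2	1539	512	55.58	8.10	Nucleus
KoWRKY26	GWHGACBH008472	IId	9	1272	423	46.08	5.43	Nucleus
KoWRKY27	GWHGACBH008891	IIb	9	1650	549	58.80	6.87	Nucleus
KoWRKY28	GWHGACBH008978	IIc	9	531	176	20.19	9.67	Nucleus
KoWRKY29	GWHGACBH009250	I	12	1431	476	51.60	5.75	Nucleus
KoWRKY30	GWHGACBH009302	IIb	12	1926	641	69.08	6.00	Nucleus
KoWRKY31	GWHGACBH009474	IIc	12	966	321	35.77	8.12	Nucleus
KoWRKY32	GWHGACBH009540	IIc	12	894	297	32.66	6.67	Nucleus
KoWRKY33	GWHGACBH009550	IId	12	858	285	32.38	4.46	Nucleus
KoWRKY34	GWHGACBH009725	IIe	12	1065	354	39.93	9.69	Nucleus
KoWRKY35	GWHGACBH010316	I	6	2181	726	78.60	6.08	Nucleus
KoWRKY36	GWHGACBH010385	I	6	1680	559	60.62	6.40	Nucleus
KoWRKY37	GWHGACBH010420	IIb	6	1047	348	37.78	8.75	Nucleus
KoWRKY38	GWHGACBH010479	IIc	6	618	205	23.46	7.64	Nucleus
KoWRKY39	GWHGACBH010849	IIe	6	1143	380	41.33	9.61	Nucleus
KoWRKY40	GWHGACBH011057	I	1	2100	699	75.95	5.76	Nucleus
KoWRKY41	GWHGACBH011286	IIe	1	1389	462	50.67	10.26	Nucleus
KoWRKY42	GWHGACBH012351	IId	11	1308	435	47.38	5.33	Nucleus
KoWRKY43	GWHGACBH012792	IId	4	942	313	34.20	9.74	Nucleus
KoWRKY44	GWHGACBH013356	IIe	8	702	233	26.40	9.81	Nucleus
KoWRKY45	GWHGACBH013438	III	8	1035	344	38.33	5.57	Nucleus
KoWRKY46	GWHGACBH013593	IIc	8	936	311	34.30	6.55	Nucleus
KoWRKY47	GWHGACBH013762	IIc	8	960	319	35.39	8.05	Nucleus
KoWRKY48	GWHGACBH013975	IIb	8	1710	569	62.07	6.06	Nucleus
KoWRKY49	GWHGACBH014415	IId	15	984	327	36.00	5.38	Nucleus
KoWRKY50	GWHGACBH014450	III	15	1026	341	38.33	6.09	Nucleus
KoWRKY51	GWHGACBH015228	IIb	16	1788	595	64.24	7.15	Nucleus
KoWRKY52	GWHGACBH015626	I	16	1770	589	64.55	6.79	Nucleus
KoWRKY53	GWHGACBH016027	IId	15	1335	444	48.49	5.15	Nucleus
KoWRKY54	GWHGACBH016181	IIc	15	867	288	32.27	5.92	Nucleus
KoWRKY55	GWHGACBH016469	I	1	1716	571	62.72	6.58	Nucleus
KoWRKY56	GWHGACBH016668	I	1	1416	471	51.77	8.44	Nucleus
KoWRKY57	GWHGACBH016971	III	1	945	314	35.35	6.08	Nucleus
KoWRKY58	GWHGACBH017668	IIb	12	1548	515	55.33	8.90	Nucleus
KoWRKY59	GWHGACBH017748	III	12	1059	352	39.06	5.90	Nucleus
KoWRKY60	GWHGACBH017774	IId	12	1056	351	37.97	6.10	Nucleus
KoWRKY61	GWHGACBH018126	I	17	1656	551	61.00	7.25	Nucleus
KoWRKY62	GWHGACBH018261	IId	17	750	249	27.56	7.05	Nucleus
KoWRKY63	GWHGACBH018617	III	11	1029	342	38.52	5.32	Nucleus
KoWRKY64	GWHGACBH019047	IIa	18	975	324	35.83	7.99	Nucleus
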