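id	quasi_smiles	endpoint	set	dcw	calc	defect_sum	ad
5	[Ag][nm312][24h][IC50][THP-1]	-3.593	P	2.2559	-3.6191	1.0553	YES
6	[Ag][nm5][24h][EC50][MCF-7]	-5.334	A	-1.577	-5.3221	2.0405	YES
7	[Ag][nm5][24h][EC50][HepG2]	-5.263	C	-0.8541	-5.0009	2.0405	YES
8	[Ag][nm5][24h][EC50][A549]	-5.033	P	-0.2091	-4.7143	1.0472	YES
9	[Ag][nm20][24h][EC50][A549]	-4.035	C	2.7579	-3.3961	0.0632	YES
10	[Ag][nm50][24h][EC50][A549]	-3.91	V	3.523	-3.0562	1.0472	YES
11	[Ag][nm20][24h][EC50][MCF-7]	-3.878	A	1.3899	-4.0039	1.0565	YES
12	[Ag][nm20][24h][EC50][HepG2]	-3.627	P	2.1129	-3.6827	1.0565	YES
13	[Ag][nm50][24h][EC50][HepG2]	-3.507	A	2.878	-3.3427	2.0405	YES
14	[Ag][nm50][24h][EC50][MCF-7]	-3.356	P	2.155	-3.664	2.0405	YES
15	[Al_2_O_3_][nm31][24h][ec50][A549]	-2.009	P	5.0528	-2.3765	2.0171	YES
18	[Al_2_O_3_][nm40–68][24h][IC50][THP-1]	-2.181	A	5.1653	-2.3265	2.0375	YES
21	[Bi_2_O_3_][nm149][24h][LC50][A549]	-3.793	A	1.8978	-3.7782	3.0131	No
22	[Bi_2_O_3_][nm149][24h][LC50][HepG2]	-3.668	V	1.2528	-4.0648	4.0063	No
23	[CeO_2_][nm14][24h][ec50][A549]	-2.236	C	3.5063	-3.0636	2.0171	YES
25	[CeO_2_][nm33,4][24h][IC50][THP-1]	-2.557	P	3.2467	-3.1789	2.0375	YES
26	[CeO_2_][nm-][24h][LD50][A549]	-2.236	P	4.8429	-2.4697	1.0209	YES
27	[CeO_2_][nm-][48h][LD50][A549]	-2.236	C	3.7565	-2.9524	1.0307	YES
30	[Co][nm20][24h][IC50][THP-1]	-2.554	P	3.8171	-2.9255	1.0535	YES
31	[Co_3_O_4_][nm9,2][24h][IC50][Caco2]	-3.292	A	3.384	-3.1179	2.0478	YES
32	[Co_3_O_4_][nm9,2][24h][IC50][A549]	-3.265	V	4.2995	-2.7112	2.0258	YES
33	[Co_3_O_4_][nm-][12h][ec50][A549]	-3.359	A	3.0885	-3.2492	1.0689	YES
34	[Co_3_O_4_][nm-][108][ec50][A549]	-3.351	V	2.9873	-3.2942	1.0519	YES
35	[Co_3_O_4_][nm-][36h][ec50][A549]	-3.348	P	3.0404	-3.2706	2.0176	YES
36	[Co_3_O_4_][nm-][60h][ec50][A549]	-3.341	V	3.1083	-3.2404	2.0176	YES
42	[Cu][nm90][24h][IC50][THP-1]	-4.05	C	2.8851	-3.3396	2.0375	YES
44	[Cu][nm22,9][24h][IC50][THP-1]	-2.747	C	3.0525	-3.2652	2.0375	YES
48	[Cu_2_O][nm83–94][24h][IC50][THP-1]	-4.244	A	2.057	-3.7075	2.0375	YES
49	[CuO][nm48][24h][ec50][A549]	-2.901	V	3.4861	-3.0726	0.0504	YES
50	[CuO][nm11,9][24h][IC50][Caco2]	-3.8	P	2.3263	-3.5879	1.0812	YES
51	[CuO][nm11,9][24h][IC50][A549]	-3.624	C	3.2418	-3.1811	1.0592	YES
52	[CuO][nm42][18h][EC50][A549]	-3.6	A	0.429	-4.4308	2.0565	YES
58	[CuO][nm45,4][24h][IC50][THP-1]	-3.808	C	3.0629	-3.2606	1.0709	YES
59	[CuO][nm30][24h][IC50][THP-1]	-3.648	V	2.9429	-3.3139	1.0709	YES
64	[CuO][nm > 50][24h][IC50][A549]	-3.423	V	3.1342	-3.2289	0.0592	YES
65	[CuO][nm-][60h][ec50][Caco2]	-3.419	C	2.3452	-3.5795	1.073	YES
66	[CuO][nm-][108][ec50][Caco2]	-3.402	C	2.2242	-3.6332	0.1073	YES
67	[CuO][nm-][36h][ec50][A549]	-3.394	V	3.1928	-3.2029	1.051	YES
68	[CuO][nm-][108][ec50][A549]	-3.342	A	3.1397	-3.2265	0.0852	YES
69	[CuO][nm-][216][ec50][Caco2]	-3.332	V	1.8852	-3.7838	0.0981	YES
70	[CuO][nm-][216][ec50][A549]	-3.33	A	2.8007	-3.3771	0.0761	YES
71	[CuO][nm-][60h][ec50][A549]	-3.328	A	3.2607	-3.1727	1.051	YES
72	[CuO][nm-][12h][ec50][A549]	-3.319	C	3.2409	-3.1815	0.1022	YES
73	[CuO][nm-][36h][ec50][Caco2]	-3.314	V	2.2773	-3.6096	1.073	YES
74	[CuO][nm-][24h][ec50][A549]	-3.259	A	4.0369	-2.8278	0.0573	YES
75	[CuO][nm-][24h][ec50][Caco2]	-2.832	C	3.1214	-3.2346	0.0793	YES
76	[Fe_2_O_3_][nm39][24h][ec50][A549]	-2.204	V	4.6853	-2.5397	1.0171	YES
77	[Fe_2_O_3_][nm-][24h][LD50][A549]	-2.204	V	6.0495	-1.9337	1.0209	YES
78	[Fe_2_O_3_][nm-][48h][LD50][A549]	-2.204	A	4.9631	-2.4164	1.0307	YES
79	[MgO][nm20][24h][ec50][A549]	-1.602	A	6.4904	-1.7378	1.0331	YES
80	[Mn_3_O_4_][nm14,9][24h][IC50][Caco2]	-3.536	V	2.6535	-3.4425	2.0478	YES
81	[Mn_3_O_4_][nm14,9][24h][IC50][A549]	-3.226	C	3.569	-3.0357	2.0258	YES
82	[Mn_3_O_4_][nm-][108][ec50][Caco2]	-4.044	A	1.3911	-4.0034	1.0739	YES
83	[Mn_3_O_4_][nm-][216][ec50][Caco2]	-3.899	V	1.0522	-4.1539	1.0648	YES
84	[Mn_3_O_4_][nm-][108][ec50][A549]	-3.857	P	2.3066	-3.5966	1.0519	YES
85	[Mn_3_O_4_][nm-][60h][ec50][Caco2]	-3.839	V	1.5121	-3.9496	2.0396	YES
86	[Mn_3_O_4_][nm-][60h][ec50][A549]	-3.767	P	2.4276	-3.5428	2.0176	YES
87	[Mn_3_O_4_][nm-][216][ec50][A549]	-3.687	A	1.9677	-3.7472	1.0428	YES
88	[Mn_3_O_4_][nm-][36h][ec50][A549]	-3.403	V	2.3598	-3.573	2.0176	YES
89	[MoO_3_][nm100][24h][ec50][A549]	-2.158	A	5.4219	-2.2125	2.0171	YES
91	[Ni][nm64–69][24h][IC50][THP-1]	-2.622	A	4.5318	-2.608	2.0375	YES
94	[NiO][nm48,9][24h][IC50][THP-1]	-4.502	P	2.783	-3.385	2.0375	YES
95	[Sb_2_O_3_][nm20,8][24h][IC50][Caco2]	-3.708	V	1.7044	-3.8642	1.0663	YES
96	[Sb_2_O_3_][nm20,8][24h][IC50][A549]	-3.563	C	2.6199	-3.4574	1.0443	YES
97	[Sb_2_O_3_][nm-][24h][ec50][Caco2]	-4.465	P	2.2649	-3.6151	0.0644	YES
98	[Sb_2_O_3_][nm-][48h][ec50][Caco2]	-4.465	P	1.1785	-4.0978	0.0741	YES
99	[Sb_2_O_3_][nm-][72][ec50][Caco2]	-4.465	A	0.3668	-4.4585	1.0581	YES
100	[Sb_2_O_3_][nm-][216][ec50][A549]	-4.123	A	1.9442	-3.7576	0.0612	YES
101	[Sb_2_O_3_][nm-][60h][ec50][Caco2]	-3.886	P	1.4887	-3.96	1.0581	YES
102	[Sb_2_O_3_][nm-][108][ec50][A549]	-3.88	V	2.2832	-3.607	0.0704	YES
103	[Sb_2_O_3_][nm-][108][ec50][Caco2]	-3.79	C	1.3677	-4.0138	0.0924	YES
104	[Sb_2_O_3_][nm-][216][ec50][Caco2]	-3.782	C	1.0287	-4.1644	0.0832	YES
105	[Sb_2_O_3_][nm-][60h][ec50][A549]	-3.694	V	2.4042	-3.5533	1.0361	YES
106	[Sb_2_O_3_][nm-][36h][ec50][Caco2]	-3.641	P	1.4208	-3.9901	1.0581	YES
107	[Sb_2_O_3_][nm-][36h][ec50][A549]	-3.538	V	2.3363	-3.5834	1.0361	YES
108	[SnO_2_][nm21][24h][ec50][A549]	-2.179	P	4.4986	-2.6227	2.0171	YES
111	[SnO_2_][nm33][24h][IC50][THP-1]	-2.429	P	2.7228	-3.4117	2.0375	YES
112	[TiO_2_][nm30–50][24h][ec50][A549]	-1.903	A	5.4703	-2.191	2.0171	YES
114	[TiO_2_][nm5–15][24h][ec50][A549]	-1.903	P	5.2689	-2.2805	2.0171	YES
120	[TiO_2_][nm12,2][24h][IC50][THP-1]	-1.877	P	4.7545	-2.509	2.0375	YES
121	[TiO_2_][nm-][24h][LD50][A549]	-1.903	V	6.5859	-1.6953	1.0209	YES
122	[TiO_2_][nm-][48h][LD50][A549]	-1.903	A	5.4994	-2.178	1.0307	YES
123	[WO_3_][nm30][24h][ec50][A549]	-2.365	C	3.4752	-3.0774	2.0171	YES
124	[Y_2_O_3_][nm33][24h][ec50][A549]	-2.354	P	3.8498	-2.911	2.0171	YES
126	[ZnO][nm21][24h][ec50][A549]	-2.908	A	4.6905	-2.5375	1.0509	YES
127	[ZnO][nm19,7][24h][IC50][A549]	-3.512	P	3.1916	-3.2034	1.0597	YES
128	[ZnO][nm19,7][24h][IC50][Caco2]	-3.428	C	2.2761	-3.6102	1.0817	YES
132	[ZnO][nm53,6][24h][IC50][THP-1]	-2.999	V	2.6149	-3.4596	0.0714	YES
133	[ZnO][nm-][48h][LD50][A549]	-3.033	P	3.5956	-3.0239	0.0645	YES
134	[ZnO][nm-][24h][LD50][A549]	-2.511	C	4.6821	-2.5412	0.0548	YES
139	[ZnO][nm > 50][24h][IC50][A549]	-3.13	V	2.9661	-3.3036	0.0597	YES
140	[ZnO][nm-][216][ec50][A549]	-3.295	P	2.6326	-3.4518	0.0766	YES
141	[ZnO][nm-][36h][ec50][A549]	-3.277	C	3.0247	-3.2776	1.0515	YES
142	[ZnO][nm-][60h][ec50][A549]	-3.246	V	3.0925	-3.2474	1.0515	YES
143	[ZnO][nm-][108][ec50][A549]	-3.238	C	2.9715	-3.3012	0.0858	YES
144	[ZnO][nm-][60h][ec50][Caco2]	-3.189	V	2.177	-3.6542	1.0735	YES
145	[ZnO][nm-][216][ec50][Caco2]	-3.122	C	1.7171	-3.8585	0.0986	YES
146	[ZnO][nm-][108][ec50][Caco2]	-3.113	C	2.056	-3.7079	0.1078	YES
147	[ZnO][nm-][36h][ec50][Caco2]	-3.09	C	2.1092	-3.6843	1.0735	YES
148	[ZnO][nm-][12h][ec50][A549]	-2.838	A	3.0727	-3.2562	0.1028	YES
149	[ZrO_2_][nm20–30][24 h][ec50][A549]	-2.09	C	5.5291	-2.1649	2.0171	YES
150	[ZrO_2_][nm32][24 h][IC50][THP-1]	-2.334	A	5.3352	-2.251	2.0375	YES
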