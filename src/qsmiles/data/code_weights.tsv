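code	group	correlation_weight	defect
[108m].......	Exposure time(minutes or hours)	-0.4525	0.0343
[12h].......	-	-0.3037	0.0513
[216].......	-	-0.1135	0.0251
[18h].......	-	0.0	1.0
[24h].......	-	-0.2873	0.0063
[36h].......	-	0.0	1.0
[48h].......	-	-0.3258	0.016
[60h].......	-	0.0	1.0
[72m]........	-	0.0	1.0
[Ag]........	Types of nanoparticles	-0.4207	0.0178
[Al_2_O_3_].....	-	0.0	1.0
[Bi_2_O_3_].....	-	0.0	1.0
[CeO_2_]......	-	0.0	1.0
[Co_3_O_4_].....	-	-0.398	1.0
[Co]........	-	0.0	1.0
[Cu_2_O]......	-	0.0	1.0
[CuO].......	-	0.4879	0.0333
[Cu]........	-	0.0	1.0
[Fe_2_O_3_].....	-	0.0	1.0
[MgO].......	-	0.0	1.0
[Mn_3_O_4_].....	-	0.0	1.0
[Mn_3_O_4_].....	-	0.0299	1.0
[MoO_3_]......	-	0.0	1.0
[NiO].......	-	0.0	1.0
[Ni]........	-	0.0	1.0
[Sb_2_O_3_].....	-	0.3814	0.0185
[SnO_2_]......	-	0.0	1.0
[Y_2_O_3_]......	-	0.0	1.0
[TiO_2_]......	-	0.4736	1.0
[WO_3_].......	-	0.0	1.0
[ZnO].......	-	0.0698	0.0338
[ZrO_2_]......	-	0.0	1.0
[nm100].....	Size of nanoparticle in nm	0.0	1.0
[nm11,9]....	-	0.0	1.0
[nm12,2]....	-	0.0	1.0
[nm14,9]....	-	0.0	1.0
[nm−].......	-	-0.3009	0.0069
[nm149].....	-	0.0	1.0
[nm14]......	-	0.0	1.0
[nm19,7]....	-	0.0	1.0
[nm20,8]....	-	0.0	1.0
[nm20–30]...	-	0.0	1.0
[nm22,9]....	-	0.0	1.0
[nm20]......	-	0.4612	0.016
[nm21]......	-	0.0	1.0
[nm30–50]...	-	0.0	1.0
[nm312].....	-	0.0	1.0
[nm33,4]....	-	0.0	1.0
[nm30]......	-	0.0	1.0
[nm31]......	-	0.0	1.0
[nm32]......	-	0.0	1.0
[nm33]......	-	0.0	1.0
[nm40–68]...	-	0.0	1.0
[nm45,4]....	-	0.0	1.0
[nm42]......	-	0.0	1.0
[nm5–15]...	-	0.0	1.0
[nm48,9]....	-	0.0	1.0
[nm50]......	-	0.0	1.0
[nm64–69]...	-	0.0	1.0
[nm83–94]...	-	0.0	1.0
[nm9,2].....	-	0.0	1.0
[nm90]......	-	0.0	1.0
[nm5].......	-	0.0	1.0
[MCF-7].....	Cell line MCF-7 (breast cancer)	0.1888	1.0
[A549]......	Cell line A549 (lung cancer)	0.1817	0.0068
[THP-1].....	Cell line THP-1 (leukemia)	0.393	0.0185
[HepG2].....	Cell line hepG2 (hepatoma)	0.0	1.0
[Caco2].....	Cell line Caco2 (cervical cancer)	-0.3912	0.0288
[EC50]......	concentration that gives 50% of the maximal response	0.3444	0.0164
[IC50]......	Concentration that gives 50% inhibition of a biological process	0.3023	0.0128
[LC50]......	Concentration that kills 50% test animals	0.0	1.0
[LD50]......	Dose that kills 50% test animals	-0.3424	0.001
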