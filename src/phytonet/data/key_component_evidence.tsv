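component	targets	degree	response	n_studies
Quercetin (+40)	PRKCA|AKT1|ACTB|CSNK2A1|CSNK2B|PIK3CG|HSPA2|PTK2B|PPARG|BCL2L1|PPARA|LCN2	12	233,661	17
Luteolin (-44, +55)	PRKCA|AKT1|ACTB|CSNK2A1|CSNK2B|PIK3CG|HSPA2|PTK2B|PPARG|BCL2L1|PPARA|LCN2	12	90,094	23
Apigenin (-47, +58)	PRKCA|AKT1|ACTB|CSNK2A1|CSNK2B|PIK3CG|HSPA2|PTK2B	11	175,455	6
Rutin (+33)	PRKCA|ACTB|CSNK2A1|CSNK2B|PIK3CG|HSPA2|CYP2C9	7	732,202	4
HSYA (-11, +17)	PTGS1|HK1	2	4,210,682	8
Kaempferol (-42, +44)	PRKCA|AKT1|ACTB|CSNK2A1|CSNK2B|PIK3CG|HSPA2|PTK2B|PPARG|PPARA	12	876,007	5
Baicalin (-40, +51)	PRKCA|AKT1|ACTB|CSNK2A1|CSNK2B|PIK3CG|HSPA2|PTK2B	8	73,419	9
Eriodictyol (+23)	PRKCA|AKT1|ACTB|CSNK2A1|CSNK2B|PIK3CG|HSPA2|PTK2B|CYP2C9	9	306,217	2
6-hydroxyapigenin (-48, +46)	PRKCA|AKT1|ACTB|CSNK2A1|CSNK2B|PIK3CG|HSPA2|PTK2B|PPARG|BCL2L1|PPARA|LCN2	12	338,578	0
6-Hydroxykaempferol (-32, +35)	PRKCA|AKT1|ACTB|CSNK2A1|CSNK2B|PIK3CG|HSPA2|PTK2B|PPARG|BCL2L1|PPARA|LCN2	12	1,375,662	0
6-Hydroxykaempferol 3-Rutinoside-6-glucoside	ACTB|CSNK2A1|CSNK2B|PIK3CG|HSPA2|PTGS1|HK1	9	1,632,678	0
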