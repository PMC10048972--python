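gene	degree	closeness	betweenness
PRKCA	46	0.46939	0.13402
AKT1	38	0.45609	0.11656
PIK3CG	36	0.39558	0.04650
CSNK2A1	36	0.38609	0.03410
CSNK2B	36	0.38609	0.03410
HSPA2	35	0.38983	0.03284
PTGS1	27	0.38609	0.08554
MAPK1	26	0.42037	0.05791
HK1	23	0.34773	0.03794
TNF	19	0.36508	0.02730
PTK2B	19	0.34183	0.01179
INS	14	0.36842	0.01911
PPARG	13	0.35698	0.01304
IL1β	13	0.34183	0.01452
IL6	13	0.35385	0.01586
PPP3R1	13	0.37182	0.01717
PPP3CA	13	0.37182	0.01717
ATP1A1	12	0.33472	0.05071
BCL2L1	12	0.33612	0.00845
NFκBIA	11	0.35385	0.00975
PPARA	11	0.34328	0.00984
PTGS2	10	0.34773	0.01090
CASP3	10	0.33612	0.00581
TLR4	10	0.35698	0.01096
VEGFA	9	0.35076	0.00812
LCN2	8	0.32525	0.00361
PLA2G2A	8	0.34475	0.01259
EGF	8	0.33895	0.01847
CYP2C9	8	0.33612	0.00471
TRPV1	7	0.32394	0.01434
ICAM1	7	0.32924	0.00425
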