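gene_title	symbol	function	r	tc	p	probe
NDC80 homolog, kinetochore complex component (S. cerevisiae)	NDC80	Spindle check point protein	0.66	1.55	1.52E-44	204162_at
budding uninhibited by benzimidazoles 1 homolog beta (yeast)	BUB1B	Spindle check point protein	0.70	1.58	1.27E-55	203755_at
polo-like kinase 1	PLK1	Spindle check point protein	0.71	1.25	3.58E-43	202240_at
MAD2 mitotic arrest deficient-like 1 (yeast)	MAD2L1	Spindle check point protein	0.71	1.57	2.29E-55	203362_s_at
budding uninhibited by benzimidazoles 1 homolog (yeast)	BUB1	Spindle check point protein	0.70	1.64	3.45E-50	209642_at
aurora kinase A	AURKA	Spindle check point protein	0.65	1.42	2.15E-54	204092_s_at
polo-like kinase 4	PLK4	Spindle check point protein	0.56	1.18	9.30E-37	204887_s_at
budding uninhibited by benzimidazoles 3 homolog (yeast)	BUB3	Spindle check point protein	0.47	1.05	3.59E-14	201457_x_at
MAD1 mitotic arrest deficient-like 1 (yeast)	MAD1L1	Spindle check point protein	0.08	1.03	1.88E-06	204857_at
centromere protein A	CENPA	FOXM target protein	0.75	1.59	1.29E-47	204962_s_at
cell division cycle 20 homolog (S. cerevisiae)	CDC20	FOXM target protein	0.75	1.66	1.09E-57	202870_s_at
aurora kinase B	AURKB	FOXM target protein	0.73	1.43	1.81E-44	209464_at
baculoviral IAP repeat-containing 5	BIRC5	FOXM target protein	0.73	1.62	5.74E-56	202095_s_at
NIMA (never in mitosis gene a)- related kinase 2	NEK2	FOXM target protein	0.69	1.74	1.32E-57	204641_at
centromere protein F, 350/400kDa (mitosin)	CENPF	FOXM target protein	0.67	1.47	1.01E-55	207828_s_at
cell division cycle 25 homolog B (S. pombe)	CDC25B	FOXM target protein	0.11	1.02	0.001216	201853_s_at
mitochondrial ribosomal protein 63	MRP63	FOXM target protein	0.04	0.99	0.400757	204387_x_at
antigen identified by monoclonal antibody Ki-67	MKI67	cell cycle marker proteins (KI-67)	0.67	1.40	8.04E-49	212021_s_at
cell division cycle 25 homolog C (S. pombe)	CDC25C	cell cycle marker proteins (CDC25)	0.53	1.27	3.49E-41	205167_s_at
cyclin-dependent kinase 1	CDK1	cell cycle marker proteins (CDC2)	0.70	1.39	2.03E-49	203214_x_at
cyclin B2	CCNB2	cell cycle marker proteins	0.75	1.54	9.85E-56	202705_at
cyclin B1	CCNB1	cell cycle marker proteins	0.74	1.61	2.68E-57	214710_s_at
cyclin A2	CCNA2	cell cycle marker proteins	0.72	1.62	8.53E-49	203418_at
Ubiquitin specific peptidase 22	USP22	cell cycle marker proteins	0.19	1.02	7.11E-06	216964_at
cyclin D1	CCND1	cell cycle marker proteins	0.19	0.99	0.436576	208711_s_at
CDC28 protein kinase regulatory subunit 1B	CKS1B	CDKI proteins degradation	0.64	1.17	1.09E-46	201897_s_at
S-phase kinase-associated protein 2 (p45)	SKP2	CDKI proteins degradation	0.61	1.16	1.29E-25	203625_x_at
cyclin-dependent kinase inhibitor 1B (p27, Kip1)	CDKN1B	CDK inhibitor	0.05	0.98	0.021125	209112_at
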