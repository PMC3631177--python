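gene_title	symbol	probe	r	go_definition	tc	p
triosephosphate isomerase 1	TPI1	213011_s_at	0.79	glycolysis	1.09	5.06E-45
non-SMC condensinI complex, subunit D2	NCAPD2	201774_s_at	0.79	cell cycle	1.19	8.33E-35
cell division cycle associated 3	CDCA3	221436_s_at	0.78	cell cycle	1.27	3.05E-50
forkhead box M1	FOXM1	202580_x_at	0.77	cell cycle	1.54	5.89E-49
TPX2, microtubule-associated, homolog (Xenopus laevis)	TPX2	210052_s_at	0.76	cell cycle	1.62	9.96E-57
centromere protein A	CENPA	204962_s_at	0.75	centromere protein	1.59	1.29E-47
karyopherin alpha 2 (RbAG cohort 1, importin alpha 1)	KPNA2	211762_s_at	0.75	cell cycle	1.16	4.99E-43
glucose-6-phosphate isomerase	GPI	208308_s_at	0.75	glycolysis	1.11	5.81E-44
cyclin B2	CCNB2	202705_at	0.75	cell cycle	1.54	9.85E-56
cell division cycle 20 homolog (S. cerevisiae)	CDC20	202870_s_at	0.75	cell cycle	1.66	1.09E-57
cyclin B1	CCNB1	214710_s_at	0.74	cell cycle	1.61	2.68E-57
RAD51 associated protein 1	RAD51AP1	204146_at	0.74	DNA repair	1.32	9.97E-43
solute carrier family 2 (facilitated glucose transporter), member 1	SLC2A1	201250_s_at	0.74	glucose transport	1.45	1.02E-46
ribonucleotide reductase M2	RRM2	209773_s_at	0.74	DNA replication	1.56	2.01E-54
aurora kinase B	AURKB	209464_at	0.73	cell cycle	1.43	1.81E-44
replication factor C (activator 1) 4, 37kDa	RFC4	204023_at	0.73	DNA replication	1.24	1.91E-38
proteasome (prosome, macropain) 26S subunit, non-ATPase, 2	PSMD2	200830_at	0.73	cell cycle	1.06	2.69E-26
kinesin family member 4A	KIF4A	218355_at	0.73	microtubule-based movement	1.63	1.52E-56
baculoviral IAP repeat-containing 5	BIRC5	202095_s_at	0.73	cell cycle	1.62	5.74E-56
kinesin family member 2C	KIF2C	209408_at	0.72	cell cycle	1.42	6.65E-54
cyclin-dependent kinase inhibitor 3	CDKN3	209714_s_at	0.72	cell cycle	1.53	2.16E-54
ubiquitin-conjugating enzyme E2S	UBE2S	202779_s_at	0.72	cell cycle	1.17	3.38E-29
family with sequence similarity 83, member D	FAM83D	225687_at	0.72	cell cycle	1.40	5.67E-35
cell division cycle 45 homolog (S. cerevisiae)	CDC45	204126_s_at	0.72	cell cycle	1.34	5.28E-43
cyclin A2	CCNA2	203418_at	0.72	cell cycle	1.62	8.53E-49
protein regulator of cytokinesis 1	PRC1	218009_s_at	0.72	cell cycle	1.47	7.11E-51
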