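step	gene_title	symbol	tc	p	probe
G1	hexokinase 2	HK2	1.05	0.0007	202934_at
G2	glucose-6-phosphate isomerase	GPI	1.11	5.81E-44	208308_s_at
G3	phosphofructokinase, liver	PFKP	1.14	8.71E-35	201037_at
G4	aldolase A, fructose-bisphosphate	ALDOA	1.07	3.26E-46	200966_x_at
G5	triosephosphate isomerase 1	TPI1	1.09	1.26E-45	200822_x_at
G6	glyceraldehyde-3-phosphate dehydrogenase	GAPDH	1.07	1.44E-57	212581_x_at
G7	phosphoglycerate kinase 1	PGK1	1.05	1.75E-28	200738_s_at
G7	phosphoglycerate kinase 2	PGK2	1.05	1.65E-12	217009_at
G8	phosphoglycerate mutase family member 5	PGAM5	1.1	3.27E-24	1555943_at
G8	phosphoglycerate mutase 1 (brain)	PGAM1	1.04	1.18E-23	200886_s_at
G8	phosphoglycerate mutase 2 (muscle)	PGAM2	1.05	2.92E-07	205736_at
G9	enolase 1, (alpha)	ENO1	1.09	6.09E-45	201231_s_at
G9	enolase 2 (gamma, neuronal)	ENO2	1.11	3.71E-16	201313_at
G9	enolase 3 (beta, muscle)	ENO3	1.06	5.41E-10	204483_at
G10	pyruvate kinase, muscle	PKM2	1.09	1.50E-25	201251_at
BP-1.1	pyruvate carboxylase	PC	1.15	1.90E-32	204476_s_at
BP-1.2	phosphoenolpyruvate carboxykinase 1 (soluble)	PCK1	1.01	0.0048	208383_s_at
BP-2	fructose-1,6-bisphosphatase 1	FBP1	0.84	8.45E-38	209696_at
BP-3	glucose-6-phosphatase, catalytic subunit	G6PC	1	0.1092	206952_at
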