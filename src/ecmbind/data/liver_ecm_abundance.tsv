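protein_id	go_accession	mw_kda	conc_control_uM	conc_ccl4_uM	printed_log2fc
Col 1a1	CO1A1	138	3.60	6.42	0.83
Col 1a2	CO1A2	130	2.55	4.25	0.74
Col 3a1	CO3A1	139	0.75	1.64	1.13
Col 4a1	CO4A1	161	0.20	0.23	-0.24
Col 4a2	CO4A2	167	0.46	0.28	-0.71
Col 5a1	CO5A1	184	0	0.05	11.80
Col 5a3	Q9JLI2	172	0	0.06	11.90
Col 18a1	E9QPX1	182	0.07	0	-11.81
Dermatopontin	DERM	24	0	7.11	16.06
Fibronectin	FINC	273	0.18	0.47	1.40
Fibrinogen beta chain	FIBB	55	3.13	0.56	-2.48
Fibrinogen gamma chain	FIBG	49	5.94	1.94	-0.45
Galectin-1	LEG1	15	8.45	21.18	1.33
Galectin-3	LG3BP	64	0	0.63	13.97
von Willebrand factor A	VMA5A	87	0.33	0.84	1.33
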