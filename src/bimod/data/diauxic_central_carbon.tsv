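pathway	loci	reaction_id	log_fc	sa_module	greedy_module	expert_flag
gly_gng_top	NTH1,2, ATH1	2868	1.87	u2	u2	1
gly_gng_top	TPS1,2, TSL1, TPS3	2870	1.21	0	u2	1
gly_gng_top	GSY1,2, GLG1,2	3204	2.35	u2	u2	1
gly_gng_top	GLC3	2663	2.87	u2	u2	1
gly_gng_top	UGP1	3729	1.01	u2	0	1
gly_gng_top	GDB1	3154	2.6	u2	u2	1
gly_gng_top	PGM1,2	3518	1.56	u2	u2	1
gly_gng_top	PGI1	3160	0.48	0	0	0
gly_gng_top	GPH1	3205	0.43	u2	0	0
gly_gng_top	FBP1	3140	3.84	0	u2	1
gly_gng_top	HXK1, GLK1, HXK2	3230	0.18	0	u2	1
tca_cycle	PCK1	3514	3.88	u1	0	1
tca_cycle	PYC1,2	3594	1.59	u1	0	1
tca_cycle	PDA1,2, PDB1, LPD1, PDX1	3597	0.1	u1	0	0
tca_cycle	ACS1,2	2785	3.7	u1	u1	1
tca_cycle	ALD2	2860	2.25	0	0	1
tca_cycle	CIT1	2985	2.72	u1	u1	1
tca_cycle	ACO1	2965	2.63	u1	u1	1
tca_cycle	IDH1,2	3286	1.49	u1	0	1
tca_cycle	KGD1,2, LPD1	3462	2.17	u1	u1	1
tca_cycle	LSC2	3660	0.71	u1	u1	1
tca_cycle	SDH1,2,3,4	3658	2.53	u1	u1	1
tca_cycle	FUM1	3142	1.89	u1	0	1
tca_cycle	MDH1	3346	2.57	u1	u1	1
tca_cycle	IDP2	3287	3.27	u1	u1	1
tca_cycle	ICL1	3290	3.7	u1	u1	1
tca_cycle	MLS1	3349	3.22	u1	u1	1
tca_cycle	MDH2	3345	1.38	u1	0	1
connection	PFK1, PFK2	3516	-1.02	d1	0	-1
connection	FBA1	3010	-1.25	d1	0	-1
connection	TPI1	3698	-1.12	d1	0	-1
connection	TDH1,2,3	3182	-0.55	0	0	0
connection	PGK1	3522	-0.51	0	0	0
connection	GPM1	3523	-1.72	d1	0	-1
connection	ENO1,2	3055	-1.18	d1	0	-1
connection	PDC1,5,6	3595	-1.91	0	d1	-1
connection	PYK1	3598	-1.81	d1	d1	-1
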