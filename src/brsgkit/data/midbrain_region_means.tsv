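segment	gene	rule	HPC	HPT	STR	MRN	VTA	tsi_reference
VTA	Tlcd1	single	214.57	142.88	20.74	15.01	473.22	0.55
VTA	Loxl2	single	1.03	1.10	1.21	0.86	16.00	0.79
VTA	Dbh	single	0.29	0.05	0.01	3.89	16.42	0.79
MRN	Crh	single	0.79	1.99	0.40	21.17	4.96	0.72
MRN	Pde12	single	13.72	3.24	16.88	81.78	3.52	0.69
MRN	Actr5	single	2.89	3.63	3.58	97.07	2.84	0.88
MRN	Fam210a	single	52.14	3.66	3.16	102.94	4.00	0.62
MRN	Rtl1	single	2.05	6.46	4.55	152.14	3.21	0.90
MRN/VTA	Slc6a5	combined	0.03	0.04	0.03	84.86	31.97	1.00
MRN/VTA	Mab21l2	combined	0.09	0.51	0.08	21.92	10.34	0.98
MRN/VTA	Rln3	combined	0.03	0.26	0.05	29.45	14.85	0.99
MRN/VTA	Glra1	combined	0.08	8.29	0.36	85.35	51.80	0.94
MRN/VTA	Lamp5	combined	12.31	6.15	37.59	144.49	53.47	0.78
MRN/VTA	Nefh	combined	18.10	26.01	16.10	299.94	220.86	0.90
MRN/VTA	Nefl	combined	206.83	145.48	137.48	820.72	684.99	0.75
MRN/VTA	Nefm	combined	66.62	57.71	73.11	598.01	507.12	0.85
MRN/VTA	Cplx1	combined	234.47	113.82	284.92	778.27	555.21	0.68
MRN/VTA	Fth1	combined	2170.92	1536.80	2882.29	4405.25	3310.33	0.54
MRN/VTA	Atp1a3	combined	778.55	768.97	592.48	1293.45	1000.71	0.52
MRN/VTA	Mbp	combined	1033.04	1080.91	2797.41	4590.89	3633.36	0.63
MRN/VTA	Snap25	combined	715.33	501.60	502.25	1307.61	1046.86	0.58
MRN/VTA	Ckb	combined	505.70	650.24	1216.06	1329.61	1084.69	0.50
MRN/VTA	Gnas	combined	634.95	1184.41	315.21	1345.01	1113.15	0.54
MRN/VTA	Slc6a9	combined	14.11061	50.1118	28.1854	110.2638	88.92087	0.68
MRN/VTA	Tph2	combined	0.296341	0.084168	0.20817	11.80536	16.09617	0.98
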