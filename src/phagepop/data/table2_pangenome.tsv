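cluster_id	n_phages	phage_names	lcb_min	lcb_max	n_core	core_pct	n_accessory	accessory_pct	pan
A1	17	Phage 77, 53, 75, 63, 54, 72, 64, 71, 47, 48, 59, 68, 65, 8, Henu8, G29-2, and pSf-1	16	16	28	22	98	78	126
A2	7	Phage 80, 28, 56_1, 76, Swan01, SECphi27 and EcoS_95	7	7	46	40	69	60	115
A3	4	Phages 69, 52, 56_2, and Jahat_MG145	4	4	62	73	23	27	85
B	6	Phage 73, 70, 17, 58, 74, and CEB_EC3a	6	6	27	33	54	67	81
C	10	Phage 61, T5, EASG3, HASG4, AKFV33, OSYSP, phiLLS, SP15, FFH1, and HdH2	6	10	86	37	147	63	233
D	19	Phage 60, 78, 62, 66, 79, EC6, VpaE1, XTG1, KhF1, KhF2, KhF3, HY02, Ro111lw, O157_1, O157_12, WV8, O157_11, Alf5, and AYO145A	14	17	72	39	115	61	187
E	18	Phage 30, 15, 18, HX01, KAW3E185, WFbE185, G53, APCEc01, MM02, HP3, ATK47, ATK48, O157_3, O157_6, ST0, JS09, G2285, and G2469	16	17	184	58	133	42	317
F	13	Phage 55, 11, 10, G2540-3, G29, G4500, D5505, G9062, CF2, YUEEL01, fFiEco06, ACG_C40, and OE55055	5	5	197	59	136	41	333
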