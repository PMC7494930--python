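name	region	farm_id	host	genome_size	gc	n_cds	related_ref	family	subfamily	genus	cluster_wgs	cluster_tls	cluster_pp	cluster_exo	suspect_typo
Phage 47	OVL	15	C600	51063	43.6	83	G29-2	Siphoviridae	Tunavirinae	Hanrivervirus	A1	A1	A1	A1	0
Phage 48	WVL	12	C600	51031	43.7	85	Henu8	Siphoviridae	Tunavirinae	Hanrivervirus	A1	A1	A1	A1	0
Phage 53	WVL	10	K514	50835	44.2	87	G29-2	Siphoviridae	Tunavirinae	Hanrivervirus	A1	A1	A1	A1	0
Phage 54	WVL	14	K514	52602	43.5	88	Henu8	Siphoviridae	Tunavirinae	Hanrivervirus	A1	A1	A1	A1	0
Phage 59	LIM	22	K514	51702	43.6	85	G29-2	Siphoviridae	Tunavirinae	Hanrivervirus	A1	A1	A1	A1	0
Phage 63	OVL	19	K514	49132	44.0	79	G29-2	Siphoviridae	Tunavirinae	Hanrivervirus	A1	A2	A1	A1	0
Phage 64	OVL	19	K514	51352	43.7	85	G29-2	Siphoviridae	Tunavirinae	Hanrivervirus	A1	A1	A1	A1	0
Phage 65	OVL	19	K514	51031	43.6	83	G29-2	Siphoviridae	Tunavirinae	Hanrivervirus	A1	A1	A1	A1	0
Phage 68	OVL	21	K514	51291	43.7	84	G29-2	Siphoviridae	Tunavirinae	Hanrivervirus	A1	A1	A1	A1	0
Phage 71	OVL	19	K514	51446	43.6	85	G29-2	Siphoviridae	Tunavirinae	Hanrivervirus	A1	A1	A1	A1	0
Phage 72	OVL	17	K514	51284	43.7	84	G29-2	Siphoviridae	Tunavirinae	Hanrivervirus	A1	A1	A1	A1	0
Phage 75	OVL	20	K514	50445	44.1	88	G29-2	Siphoviridae	Tunavirinae	Hanrivervirus	A1	A1	A1	A1	0
Phage 77	ANT	6	K514	51073	44.0	85	G29-2	Siphoviridae	Tunavirinae	Hanrivervirus	A1	A1	A1	A1	0
Phage 8	VBR	27	C600	51031	43.6	83	pSf-1	Siphoviridae	Tunavirinae	Hanrivervirus	A1	A1	A1	A1	0
Phage 28	OVL	19	K514	52970	44.4	87	SECphi27	Siphoviridae	Tunavirinae	Swanvirus	A2	A2	A2	A2	0
Phage 56_1	ANT	1	K514	52716	44.5	86	EcoS-95	Siphoviridae	Tunavirinae	Swanvirus	A2	A2	A2	A2	0
Phage 76	WVL	11	K514	51905	45.0	93	SECphi27	Siphoviridae	Tunavirinae	Swanvirus	A2	A4	A2	A2	0
Phage 80	OVL	18	K514	52703	44.5	88	EcoS-95	Siphoviridae	Tunavirinae	Swanvirus	A2	A2	A2	A2	0
Phage 52	WVL	13	K514	53018	45.9	90	Jahat MG145	Siphoviridae	Tunavirinae	New genus	A3	A3	A3	A3	0
Phage 56_2	ANT	1	K514	50829	45.7	87	Jahat MG145	Siphoviridae	Tunavirinae	New genus	A3	A3	A3	A3	0
Phage 69	WVL	14	K514	62384	46.3	112	Jahat MG145	Siphoviridae	Tunavirinae	New genus	A3	A3	A3	A3	0
Phage 17	OVL	19	K514	45948	44.5	73	CEB_EC3a	Siphoviridae	Tunavirinae	Rtpvirus	B	B	B	B	0
Phage 58	ANT	4	K514	45387	44.3	73	CEB_EC3a	Siphoviridae	Tunavirinae	Rtpvirus	B	B	B	B	0
Phage 70	LIM	25	K514	44539	44.8	72	CEB_EC3a	Siphoviridae	Tunavirinae	Rtpvirus	B	B	B	B	0
Phage 73	OVL	17	K514	46938	44.3	76	CEB_EC3a	Siphoviridae	Tunavirinae	Rtpvirus	B	B	B	B	0
Phage 74	OVL	21	K514	46683	44.6	77	CEB_EC3a	Siphoviridae	Tunavirinae	Rtpvirus	B	B	B	B	0
Phage 61	ANT	3	K514	109866	39.2	164	T5	Siphoviridae	N/A	Tequintavirus	C	C	C	C	0
Phage 60	LIM	26	K514	86237	39.3	127	Alf5	Myoviridae	Ounavirinae	Felixounavirus	D	D	D	D	0
Phage 62	VBR	7	K514	87871	39.0	128	Alf5	Myoviridae	Ounavirinae	Felixounavirus	D	D	D	D	0
Phage 66	ANT	2	K514	90196	39.0	137	Alf5	Myoviridae	Ounavirinae	Felixounavirus	D	D	D	D	0
Phage 78	VBR	8	K514	89900	39.1	130	Alf5	Myoviridae	Ounavirinae	Felixounavirus	D	D	D	D	0
Phage 79	LIM	23	K514	89663	39.0	135	AYO145A	Myoviridae	Ounavirinae	Felixounavirus	D	D	D	D	0
Phage 15	OVL	21	K514	169586	37.7	269	MM02	Myoviridae	Tevenvirinae	Mosigvirus	E	E	E	E	0
Phage 18	OVL	19	K514	169868	37.7	271	MM02	Myoviridae	Tevenvirinae	Mosigvirus	E	E	E	E	0
Phage 30	WVL	9	K514	173384	38.0	275	O157 tp 3	Myoviridae	Tevenvirinae	Mosigvirus	E	E	E	E	0
Phage 10	ANT	5	K514	168952	35.5	268	YUEEL01	Myoviridae	Tevenvirinae	Tequatrovirus	F	F	F	F	0
Phage 11	OVL	16	K514	171370	35.5	269	fFiEco06	Myoviridae	Tevenvirinae	Tequatrovirus	F	F	F	F	0
Phage 55	LIM	24	K514	1699535	35.6	275	Phage T4	Myoviridae	Tevenvirinae	Tequatrovirus	F	F	F	F	1
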