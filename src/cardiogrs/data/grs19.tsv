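rsid	chromosome	locus	risk_allele	reference_allele	published_or	in_grs14
rs4341	17q23	ACE	G	C	1.01	0
rs662799	11q23	APOA5	G	A	1.10	1
rs1042031	2p23-24	APOB	A	G	1.01	0
rs429358	19q13.2	APOE	C	T	1.25	1
rs7412	19q13.2	APOE	C	T	1.06	1
rs10757274	9p21	CDKN2A/CDKN2B	G	A	1.23	1
rs599839	1p13.3	CELSR2/PSRC1/SORT1	A	G	1.11	1
rs708272	16q21	CETP	C	T	1.04	0
rs1746048	10q11.2	CXCL12	C	T	1.07	1
rs7025486	9q33	DAB2IP	A	G	1.04	1
rs10455872	6q26	LPA	G	A	1.32	1
rs3798220	6q26	LPA	C	T	1.28	1
rs1801177	8p22	LPL	A	G	1.09	1
rs328	8p22	LPL	C	G	1.10	1
rs17465637	1q41	MIA3	C	A	1.14	1
rs9818870	3q23.3	MRAS	T	C	1.07	1
rs1799983	7q35-36	NOS3	T	G	1.00	0
rs11591147	1p32.3	PCSK9	G	T	1.39	1
rs17228212	15q22	SMAD3	C	T	1.01	0
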