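rsid	raf	n_individuals
rs4341	0.52	1214
rs662799	0.06	1214
rs1042031	0.18	1214
rs429358	0.17	1214
rs7412	0.91	1214
rs10757274	0.48	1214
rs599839	0.78	1214
rs708272	0.56	1214
rs1746048	0.86	1214
rs7025486	0.26	1214
rs10455872	0.07	1214
rs3798220	0.02	1214
rs1801177	0.01	1214
rs328	0.90	1214
rs17465637	0.71	1214
rs9818870	0.16	1214
rs1799983	0.33	1214
rs11591147	0.99	1214
rs17228212	0.31	1214
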