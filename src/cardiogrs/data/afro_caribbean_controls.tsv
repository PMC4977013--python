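rsid	raf	n_individuals
rs4341	0.60	359
rs662799	0.13	359
rs1042031	0.15	359
rs429358	0.23	359
rs7412	0.93	359
rs10757274	0.21	359
rs599839	0.25	359
rs708272	0.76	359
rs1746048	0.53	359
rs7025486	0.32	359
rs10455872	0.01	359
rs3798220	0.01	359
rs1801177	0.001	359
rs328	0.94	359
rs17465637	0.24	359
rs9818870	0.08	359
rs1799983	0.12	359
rs11591147	1.00	359
rs17228212	0.12	359
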