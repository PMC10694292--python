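gene_symbol	log2fc	fdr
Cyp1a2	-1.69	4.07e-07
Cyp2c29	-1.92	1.01e-09
Cyp3a11	0.30	0.46
Cyp2d22	-0.18	0.23
Abcc3	1.69	3.28e-09
Abcc4	3.95	9.07e-19
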