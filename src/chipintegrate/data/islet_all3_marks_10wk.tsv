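gene	h3k4me3_log2fc	h3k27me3_log2fc	h3k27ac_log2fc	rna_log2fc	rna_fdr
Trpm5	1.27	-0.78	0.96	0.8302	0.0215
Tfam	0.90	-0.95	1.10	0.5014	0.0148
Mcf2l	1.17	-1.06	1.19	0.4669	0.0500
Slc28a2	-1.05	1.77	-0.75	-1.2177	0.0040
Tnf	-1.47	1.01	-0.95	-2.1019	0.0020
Mpz	-0.55	0.42	-0.56	-2.4936	0.0027
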