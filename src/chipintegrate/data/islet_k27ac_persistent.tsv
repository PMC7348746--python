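gene	rna_log2fc_2wk	rna_fdr_2wk	h3k27ac_log2fc_2wk	rna_log2fc_10wk	rna_fdr_10wk	h3k27ac_log2fc_10wk
Bcat2	-1.08	1.30e-2	-0.98	-1.37	1.74e-4	-0.88
Bhlha15	-2.12	8.77e-5	-0.66	-1.42	5.75e-3	-0.48
Cyp2t1	-0.99	1.14e-2	-0.63	-0.78	3.54e-2	-0.56
Dram1	-1.42	1.41e-3	-0.12	-1.92	5.29e-7	-0.76
Foxa3	-0.98	3.16e-2	-0.67	-0.92	2.37e-2	-0.47
Gpt2	-1.39	2.83e-4	-0.59	-0.91	1.67e-2	-0.77
Mast3	-1.10	2.69e-4	-0.56	-0.83	4.53e-3	-0.77
Ppard	-1.36	5.15e-5	-0.06	-1.97	7.32e-11	-0.74
Pycr1	-1.85	1.82e-4	-0.87	-1.18	2.05e-2	-0.82
Reep5	-0.92	4.49e-2	-0.41	-1.48	2.62e-5	-0.47
Tex49	-2.10	3.54e-3	-0.33	-1.93	2.48e-2	-1.35
Rnh1	-1.15	1.39e-2	-0.28	-1.97	1.32e-7	-0.56
Rnpepl1	-1.03	1.17e-3	-0.64	-1.37	9.37e-7	-0.48
Sel1l	-1.61	3.84e-3	-0.38	-1.86	9.29e-5	-0.95
Sfxn2	-1.42	2.34e-3	-0.51	-0.97	3.91e-2	-0.90
Tnip2	-0.61	3.89e-2	-0.55	-0.59	2.96e-2	-0.59
Tst	-1.26	1.41e-2	-0.14	-3.13	9.28e-14	-0.54
Ulk1	-1.03	2.87e-5	-0.41	-0.70	4.26e-3	-0.66
Wdtc1	-0.92	2.98e-3	-1.01	-0.90	1.26e-3	-0.51
Xbp1	-1.14	1.64e-2	-0.56	-1.16	4.90e-3	-0.84
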