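gene	biv_2wk_control	biv_2wk_IUGR	biv_10wk_control	biv_10wk_IUGR
Acod1	+	+	-	+
Fgf21	+	+	-	+
Serpina11	+	+	-	+
Cdh16	-	-	+	-
Lrrc27	-	-	+	-
Lrrc66	-	-	+	-
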