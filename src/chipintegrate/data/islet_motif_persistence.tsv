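mark	motif_name	consensus	p_2wk_IUGR	p_2wk_control	p_10wk_IUGR	p_10wk_control
H3K4me3	ELF3	ANCAGGAAGT	1.00 × 10^−43^	0.1	1.00 × 10^−9^	1
H3K4me3	ELF5	ACVAGGAAGT	1.00 × 10^−34^	0.1	1.00 × 10^−7^	1
H3K4me3	ERG	ACAGGAAGTG	1.00 × 10^−71^	0.1	1.00 × 10^−8^	1
H3K4me3	ETS1	ACAGGAAGTG	1.00 × 10^−48^	1	1.00 × 10^−16^	0.1
H3K4me3	ETV1	AACCGGAAGT	1.00 × 10^−80^	0.1	1.00 × 10^−11^	1
H3K4me3	ETV2	NNAYTTCCTGHN	1.00 × 10^−62^	1	1.00 × 10^−9^	0.1
H3K4me3	EWS:ERG	ATTTCCTGTN	1.00 × 10^−69^	0.1	1.00 × 10^−8^	1
H3K4me3	GABPA	RACCGGAAGT	1.00 × 10^−58^	0.1	1.00 × 10^−8^	0.1
H3K4me3	SMAD4	VBSYGTCTGG	1.00 × 10^−24^	1	1.00 × 10^−6^	1
H3K27me3	MEIS1	VGCTGWCAVB	1	1.00 × 10^−4^	1	1.00 × 10^−17^
H3K27me3	PR	VAGRACAKNCTGTBC	0.1	1.00 × 10^−11^	1	1.00 × 10^−20^
H3K27me3	OLIG2	RCCATMTGTT	1	1.00 × 10^−5^	0.1	1.00 × 10^−10^
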