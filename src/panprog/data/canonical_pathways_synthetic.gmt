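PI3K_signaling	synthetic stand-in gene set	PIK3CA	PIK3CG	PIK3R1	AKT1	AKT2	PTEN	MTOR	PDPK1	EGFR	IGF1R	MET	KIT	PDGFRA	VEGFA	BCL2	BCL2L11	MCL1	CSNK2A1	FOXO3	RICTOR
MAPK_signaling	synthetic stand-in gene set	KRAS	NRAS	HRAS	BRAF	RAF1	MAP2K1	MAP2K2	MAPK1	MAPK3	MAP3K2	EGFR	MET	KIT	PDGFRA	DUSP6	RASA1	NF1	SOS1	GRB2	FGFR1
Cell_cycle	synthetic stand-in gene set	CCND1	CCNE1	CDK4	CDK6	CDK2	RB1	E2F1	CDKN2A	CDKN1A	CDKN1B	MDM2	TP53	MYC	CCNB1	CDC25A	WEE1	PLK1	AURKA	BUB1	CHEK1
Wnt_signaling	synthetic stand-in gene set	CTNNB1	APC	AXIN1	AXIN2	GSK3B	WNT1	WNT3A	FZD1	LRP5	LRP6	TCF7	LEF1	DVL1	MYC	CCND1	DKK1	SFRP1	WIF1	RNF43	ZNRF3
P53_signaling	synthetic stand-in gene set	TP53	MDM2	MDM4	CDKN1A	BAX	PUMA	BBC3	GADD45A	SFN	ATM	ATR	CHEK1	CHEK2	TP73	SERPINB5	PERP	RRM2B	SESN1	SESN2	ZMAT3
Hippo_signaling	synthetic stand-in gene set	YAP1	WWTR1	LATS1	LATS2	STK3	STK4	SAV1	MOB1A	TEAD1	TEAD4	NF2	AMOTL1	CTGF	CYR61	AJUBA	DCHS1	FAT1	FAT4	WWC1	CSNK2A1
TGFb_signaling	synthetic stand-in gene set	TGFB1	TGFB2	TGFBR1	TGFBR2	SMAD2	SMAD3	SMAD4	SMAD7	ACVR1	ACVR2A	BMP2	BMP4	BMPR1A	BMPR2	INHBA	LTBP1	THBS1	SKP1	ZFYVE9	FOXO3
Notch_signaling	synthetic stand-in gene set	NOTCH1	NOTCH2	NOTCH3	NOTCH4	JAG1	JAG2	DLL1	DLL3	DLL4	HES1	HEY1	RBPJ	MAML1	ADAM17	PSEN1	PSEN2	NCSTN	LFNG	DTX1	NUMB
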