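gene	drug
EGFR	trastuzumab
EGFR	erlotinib
EGFR	lapatinib
VEGFA	bevacizumab
VEGFA	vandetanib
BCL2	paclitaxel
KIT	sorafenib
PDGFRA	sunitinib
MCL1	imatinib
PDPK1	celecoxib
MET	crizotinib
MET	docetaxel
IGF1R	linsitinib
AKT1	resveratrol
PIK3CG	quercetin
CSNK2A1	silmitasertib
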