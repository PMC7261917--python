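cancer_type	category
BLCA	urologic
KICH	urologic
KIRC	urologic
KIRP	urologic
PRAD	urologic
BRCA	gynecologic
CESC	gynecologic
OV	gynecologic
UCEC	gynecologic
COAD	core GI
READ	core GI
STAD	core GI
LIHC	developmental GI
LUAD	thoracic
LUSC	thoracic
LGG	CNS
HNSC	head and neck
THCA	endocrine
SKCM	melanocytic
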