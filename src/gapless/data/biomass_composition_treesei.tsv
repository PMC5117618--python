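section	key	value
total	protein	45.100
total	carbohydrate	23.190
total	chitin	7.820
total	rna	6.122
total	dna	0.912
total	gc_content	0.52
total	ergosterol	0.278
total	ash	5.100
amino_acid	Ala	2.715
amino_acid	Arg	3.944
amino_acid	Asn	1.613
amino_acid	Asp	2.677
amino_acid	Cys	0.549
amino_acid	Gln	2.063
amino_acid	Glu	3.200
amino_acid	Gly	1.649
amino_acid	His	1.346
amino_acid	Ile	2.186
amino_acid	Leu	4.101
amino_acid	Lys	2.595
amino_acid	Met	1.202
amino_acid	Phe	2.220
amino_acid	Pro	2.363
amino_acid	Ser	2.808
amino_acid	Thr	2.354
amino_acid	Trp	1.144
amino_acid	Tyr	1.846
amino_acid	Val	2.523
rna_base_fraction	A	0.247
rna_base_fraction	C	0.237
rna_base_fraction	G	0.279
rna_base_fraction	U	0.237
fatty_acid_ester	myristic	0.004
fatty_acid_ester	palmitic	0.613
fatty_acid_ester	palmitoleic	0.011
fatty_acid_ester	stearic	0.070
fatty_acid_ester	oleic	0.126
fatty_acid_ester	linoleic	1.425
fatty_acid_ester	alpha_linolenic	0.292
fatty_acid_ester	arachidic	0.004
fatty_acid_ester	lignoceric	0.005
fatty_acid_free	palmitic	0.060
fatty_acid_free	stearic	0.012
fatty_acid_free	oleic	0.107
fatty_acid_free	linoleic	0.274
lipid_class_ratio	TAG	0.52
lipid_class_ratio	PE	0.16
lipid_class_ratio	PC	0.32
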