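name	kegg_id
alpha-methyl-D-mannoside
beta-methyl-D-glucoside
Arbutin	C06186
Cellobiose	C00185
D-arabitol	C01904
D-Fructose	C00095
D-Galactose	C00124
D-Glucose	C00031
D-Mannitol	C00392
D-Mannose	C00159
D-Sorbitol	C00794
D-xylose	C00181
Esculin
Glycerol	C00116
Glycerol-1-monoacetate
L-arabinose	C00259
L-sorbose	C00247
N-acetyl-beta-D-glucosamine	C00140
Salicin	C01451
Trehalose	C01083
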