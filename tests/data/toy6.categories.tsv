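pathway	category
Dead-end pathway	Lipid metabolism
Essential biosynthesis	Amino acid metabolism
Internal cycle	Lipid metabolism
Redundant synthesis 1	Energy metabolism
Redundant synthesis 2	Energy metabolism
Transport reactions	Miscellaneous
Unique exporter pathway	Carbohydrate metabolism
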