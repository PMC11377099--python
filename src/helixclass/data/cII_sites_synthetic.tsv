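gene	site	sequence	methylated_positions	hotspot
cII	cII_h1	GGCGTCGCGCCTAGCCAGCGGAGGT	6	1
cII	cII_h2	GCCGTCGGGCGGCAAGCCGCAGGGC	6	1
cII	cII_h3	CCCCGCGCGGAGCGGGGCCGGACTG	6	1
cII	cII_h4	TGCCGCGGGGCCCCCCCGGCCTCCG	6	1
cII	cII_h5	TCGGCCGCCCGGCCCGCGGATGCGC	6	1
cII	cII_n1	GTATGCGCGTCATATGGAAGGTCTC	6	0
cII	cII_n2	ACAAGCGTAAGTATCGTTTGAGAAA	6	0
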