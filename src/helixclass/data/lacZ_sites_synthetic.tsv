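gene	site	sequence	methylated_positions	hotspot
lacZ	lacZ_h1	CGGGTCGCGGCGCTCCGCGCCCGCT	6	1
lacZ	lacZ_h2	CCACACGTATCGCACTCGGCCCCGC	6	1
lacZ	lacZ_h3	CGCCTCGGGGCCCGGGCGGCGCCGC	6	1
lacZ	lacZ_h4	GGCCGCGAGCCGGCGGCCGGGGCGC	6	1
lacZ	lacZ_h5	AGGGTCGCCCGCGTATTTGGGCTCG	6	1
lacZ	lacZ_n1	CAGACCGCTTCTGCGATTAACCTTA	6	0
lacZ	lacZ_n2	TAAAACGTCTTACTCATCATCCAGC	6	0
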