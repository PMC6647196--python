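name	chrom	position	marker_type	forward_primer	reverse_primer	product_length
InDel5	A08	532619	InDel	CGAATCCTGAACCCCAAACCTAAACC	ATCACCATGGCAACAACTCC	376
InDel6	A08	534601	InDel	CGCGAGGACTAAAATTTGAAAGTTTGGAGG	TAAGGATTGGGGCATTAACTGG	178
SSR82	A08	580404	SSR	CCTTCCATGCATATTGGAAAC	AAAGCACCCAATTTCAAGG	283
InDel9	A08	650514	InDel	GATTTCCCTTTCATCAAATATTCTATGTTAGCGACTCAAATACTTAG	TATACCATATTAGCCTCTTTC	536
SSR3590	A08	665115	SSR	AAACCCAATATATTCTGAGTTAAATGTTCACT	ATAACTAGCGGGTGGAAA	184
SSR3616	A08	742113	SSR	GGGATACCTGCAAACATTGTG	TTCATGGCCTTCCTCTCTGT	154
SSR3668	A08	773922	SSR	TGGATCGGTAATGGTAGAAAGC	AGCAAGGTCTTAGATGGCAA	240
SSR3692	A08	821505	SSR	GCTGTGAGGACATGAAACGA	TTGGTCTCCCTTTAGCAACG	222
SSR3699	A08	877473	SSR	TCGAGTTCGGTTAACTCATAACAC	CGAACACAAACTTAATTGGAA	151
SSR9	A08	877601	SSR	AAATATAACGATGTGGGTGGAA	ATGTCATGACTTAACCGAACACA	292
SSR6-38	A08	1006357	SSR	CGTCGTTGGGTACTGATCCA	CCAACCAAGCCTTTCACACG	329
SSR67	A08	1083921	SSR	AAGTGGGATATTGCCATCCAG	CTATGTTAATAGTGTCATCAAATGAA	274
SSR3741	A08	1091420	SSR	AACATGGTCAAGATAATTGCACTA	AAAGTGCATACAGATGCCAAA	244
SSR3465	A08	1478980	SSR	GCTTAGGACGGATTTGGTAAAT	GCAAGTTTGAAGGAATATAATGAA	229
SSR3257	A08	1578266	SSR	GAATACTCCCTCATCCCAATAAAT	GATCGACACTTCTTCTGTCTCA	246
SSR3291	A08	1683443	SSR	ATCCTTGTTATGCTCCGCTC	TTCAATGGACTGTGAGGGTAAA	236
SSR3370	A08	2183521	SSR	TTTGGATCGGATTTGGGTTA	GCAATCAAATCCTTGAAGCC	188
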