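gene_id	chrom	start	end	strand	cds_length	annotation
ORF1	A08	580856	581116	+	261	GLABRA2 interacting repressor
ORF2	A08	605735	606576	+	813	Probable CCR4-associated factor 1 homolog 11
ORF3	A08	607704	618632	-	2865	Serine/threonine-protein phosphatase BSL2
ORF4	A08	626811	632509	+	1770	Outer envelope protein 61
ORF5	A08	635236	638304	+	1158	E3 ubiquitin-protein ligase RHF2A
ORF6	A08	639890	642641	-	441	Succinate dehydrogenase subunit 6, mitochondrial
ORF7	A08	645188	647657	+	651	Small heat-shock protein 1
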