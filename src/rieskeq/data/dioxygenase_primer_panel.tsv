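# Reference clade-specific primer panel targeting the conserved Rieske-centre
# region of aromatic dioxygenase alpha-subunit genes.
# position: 1-based position of the primer 5' base in the model organism gene
#           (sense-strand coordinate; for R primers, the 3'-most covered base
#           arithmetic is taken from the printed amplicon size, which is
#           authoritative where the two disagree).
# amplicon_bp / gc_printed / anneal_c: published values.
set_id	role	sequence	clade	position	amplicon_bp	gc_printed	anneal_c	note
P1&2	F	AACGGYGAACTGCARAGC	I,II	331	269	44	66	nahAc,pahAc,ndoB
P1&2	R	CGTCCAACCVACGTGGTC	I,II	619		61
P4	F	CCGGAGACTTCCTGACGAC	IV	188	116	63	66	etbA1,ebdA1
P4	R	GCASACGAAYCGACGGGT	IV	322		55
P5	F	TGGACCTACAGCAACACG	V	337	101	55	67	narAa,nidA
P5	R	CCAGCGAGCCGAAGATCA	V	461		61
P6A	F	CGAGTCGGAGTTGGCCAAG	VIA,VIB	189	159	63	69	nidA,pdoA1
P6A	R	CTGTACACCCAGCCGTGGT	VIA,VIB	366		63
P6B	F	TGGCGAACTCGTGTCGGCAC	VIA,VIB	262	195	65	65	pdoA2,phdA
P6B	R	CGTCCAGRCAACCGAADAYC	VIA,VIB	476		50
P7Aa	F	ACCTACATGGGCGAAGACC	VIIAa	229	103	58	66	bphA1
P7Aa	R	GTARGTGCAGGTGAAGGCCT	VIIAa	350		55
P7Ab	F	TGGTCGCTCTTGGCTGTTAC	VIIAb	165	198	55	66	bphA
P7Ab	R	GCTTGCCGGCGATGTCGTA	VIIAb	382		63
P7Ac	F	TAYCTGACCACCTACATGG	VIIAc	220	60	47	62	ipbA1,ebdAa,cumA1
P7Ac	R	CCRCGATGCCGACATTG	VIIAc	298		59
P7B	F	CACBTGCAGCTAYCACG	IV,VIIB	349	181	53	62	bphA1,todC1,ipbA1,bpdC1
P7B	R	CATGTGGTCCATGTAGAAC	IV,VIIB	549		47
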