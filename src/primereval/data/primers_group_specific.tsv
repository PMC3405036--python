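name	sequence	orientation	pos_start	pos_end	target_group	reference	flagged	deg_printed	tm_printed
ChenBR1	CGCIWTYTACGGIAARGGIGG	forward	18	38	BR	Chen1	deg_printed_counts_inosine_as_4	512	66.6-69.8
nifH-f1-forA	GCSTTCTACGGMAAGGGTGG	forward	19	38	Fr	Brgmann1		4	63.9-66.7
nifH-a1-forA	GCRTTYTACGGYAARGGSGG	forward	19	38	AP	Brgmann1		32	60.6-69.1
nifHF	TACGGNAARGGSGGNATCGGCAA	forward	25	47	R	Laguerre1		64	66.7-73.9
primer-3	GGTATYGGYAARTGYACYAC	forward	37	56	RA	Lovell1		32	52.6-64.8
nifHf1	GGCAAGTCCACCACCCAGC	forward	43	61	Fr	Mirza1		1	67.0
Olsen1	ATYGTCGGYTGYGAYCCSAARGC	forward	106	128	AM	Olson1		64	65.0-73.6
cyanoF	CGTAGGTTGCGACCCTAAGGCTGA	forward	108	131	Cy	Olson1		1	68.8
nifH-b1-forB	GGCTGCGATCCCAAGGCTGA	forward	112	131	AB	Brgmann1		1	68.3
nifH-g1-forB	GGTTGTGACCCGAAAGCTGA	forward	112	131	GP	Brgmann1		1	64.1
nifH-c1-forB	GGWTGTGATCCWAARGCVGA	forward	112	131	AN	Brgmann1		24	58.7-64.3
nifH-a2-forB	GGCTGCGATCCGAAGGCCGA	forward	112	131	AP	Brgmann1		1	70.3
nifH-a1-forB	GGMTGCGAYCCSAARGCSGA	forward	112	131	AP	Brgmann1		32	66.2-72.7
nifH-f1-forB	GGBTGYGACCCSAASGCYGA	forward	112	131	Fr	Brgmann1		48	65.9-72.9
nifHFor	ACCCGCCTGATCCTGCACGCCAAGG	forward	136	160	MS	Soares1		1	74.7
cylnif-F	TAARGCTCAAACTACCGTAT	forward	156	175	Cs	Dyble1		2	56.2-57.9
NIFH2F	GAAGGTCGGCTACCAGAACA	forward	231	250	TB	Barbieri1		1	63.1
NIFH5R	AAGTTGATCGAGGTGATGACG	reverse	306	326	TB	Barbieri1		1	61.6
nifH-269	CCGGCCTCCTCCAGGTA	reverse	325	341	Fr	Mirza2		1	64.2
cylnif-R	ATTTAGACTTCGTTTCCTAC	reverse	356	375	Cs	Dyble1		1	54.6
NifHRev	ACGATGTAGATTTCCTGGGCCTTGTT	reverse	427	452	MS	Soares1		1	67.5
primer-4=AQE	GACGATGTAGATYTCCTG	reverse	436	453	RA	Lovell1		2	53.8-55.1
cyanoR	GCATACATCGCCATCATTTCACC	reverse	460	482	Cy	Olson1		1	63.6
nifH-f1-rev	GCGTACATSGCCATCATCTC	reverse	463	482	Fr	Brgmann1		2	62.2-62.3
nifH-b1-rev	GCGTACATGGCCATCATCTC	reverse	463	482	AB	Brgmann1		1	62.3
nifH-g1-rev	GCGTACATGGCCATCATCTC	reverse	463	482	GP	Brgmann1		1	62.3
nifH-c1-rev	GCATAYASKSCCATCATYTC	reverse	463	482	AN	Brgmann1	deg_printed_inconsistent	8	55.4-62.3
nifH-a2-rev	GCGTAGAGCGCCATCATCTC	reverse	463	482	AP	Brgmann1		1	64.0
nifH-a1-rev	GCATAGAGCGCCATCATCTC	reverse	463	482	AP	Brgmann1		1	62.0
Olsen2	ATGGTGTTGGCGGCRTAVAKSGCCATCAT	reverse	466	494	AM	Olson1		24	71.5-75.3
nifHr	CTCGATGACGGTCATCCGGC	reverse	671	690	Fr	Mirza1		1	65.9
ChenBR2	GGIKCRTAYTSGATIACIGTCAT	reverse	676	698	BR	Chen1	deg_printed_counts_inosine_as_4	1024	63.6-69.1
FGPH750	GAAGACGATCCCGACCCCGA	forward	759	778	Fr	Simonet1		1	66.8
nifHI	AGCATGTCYTCSAGYTCNTCCA	reverse	785	806	R	Laguerre1		32	63.3-68.8
FGPD913'	GGTCGGGACCTCATCCTCGA	reverse			Fr	Simonet1	beyond_reference_stop_codon	1	66.3
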