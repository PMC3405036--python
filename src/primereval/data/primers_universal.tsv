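name	sequence	orientation	pos_start	pos_end	target_group	reference	flagged	deg_printed	tm_printed
Nh21F	GCIWTYTAYGGNAARGG	forward	19	35	universal	Deslippe1		64	51.8-61.9
nifH19F	GCIWTITAYGGNAARGGNGG	forward	19	38	universal	Widmer1		128	59.5-69.5
Ueda19F	GCIWTYTAYGGIAARGGIGG	forward	19	38	universal	Ueda1		16	62.4-67.9
IGK3	GCIWTHTAYGGIAARGGIGGIATHGGIAA	forward	19	47	universal	Ando1		72	69.4-75.3
K07-F	GCGTTCTACGGTAAGGGCGGTATCGGNAAR	forward	19	48	universal	Rsch2		8	71.0-72.8
nifH4	TTYTAYGGNAARGGNGG	forward	22	38	universal	Zani1		128	49.8-63.5
primer-f	TCTACGGAAAGGGCGGTATCGG	forward	23	44	universal	FloresMireles1		1	66.5
FGPH19	TACGGCAARGGTGGNATHG	forward	25	43	universal	Simonet1		24	58.2-66.2
IGK-Poly	TACGGYAARGGBGGYATCGG	forward	25	44	universal	Poly1	renamed	24	60.3-70.6
PicenoF44	TACGG(P/K)AAKGG(P/G)GG(P/K)ATPGG	forward	25	44	universal	Piceno1	nonstandard_bases	8	
F1	TAYGGIAARGGIGGIATYGGIAARTC	forward	25	50	universal	Marusina1	deg_printed_counts_inosine_as_4	4096	60.4-74.5
MehtaF	GGHAARGGHGGHATHGGNAARTC	forward	28	50	universal	Mehta1		1296	57.4-72.9
IGK	AARGGNGGNATHGGNAA	forward	31	47	universal	Ohkuma1	linker_removed	384	62.1-72.5
nifHF-Rösch	AAAGGYGGWATCGGYAARTCCACCAC	forward	31	56	universal	Rsch1	renamed	16	66.0-71.6
röschF-1b	AAAGGYGGWATCCGYAARTCCACCAC	forward	31	56	universal	Ogilvie1	renamed;probable_sequence_error	16	66.0-71.6
RL28	GGTATYGGYAARTCSACSAC	forward	37	56	universal	Bagwell1		32	57.7-64.1
KAD3	ATHGTIGGITGYGAYCCIAARGCIGA	forward	106	131	universal	Ando1	deg_printed_inconsistent	16	70.1-76.8
469	GGNTGYGAYCCNAARGC	forward	112	128	universal	Poly1		128	53.4-67.4
nif112	GGITGTGAYCCNAAVGCNGA	forward	112	131	universal	Widmer1		96	60.9-70.4
nifH-univ-f112	GGITGYGAYCCNAAVGCNGA	forward	112	131	universal	Brgmann1		192	60.9-72.7
nifH2	TGYGAYCCNAARGCNGA	forward	115	131	universal	Zehr2		128	54.0-68.1
Kadino	TGYGAYCCIAARGCIGA	forward	115	131	universal	Poly1		8	60.2-67.9
F2	TGYGAYCCIAAIGCIGA	forward	115	131	universal	Marusina1		4	62.3-67.9
polF	TGCGAYCCSAARGCBGACTC	forward	115	134	universal	Poly1		24	63.8-70.1
nifH11	GAYCCNAARGCNGACTC	forward	118	134	universal	Yeager1		64	52.7-63.4
FGPH273'	CTCCGGGCCRCCNGAYTC	reverse	262	279	universal	Simonet1		16	63.7-70.7
nifH-2f	GMRCCIGGIGTIGGYTGYGC	forward	277	296	universal	Fedorov1		16	69.2-78.3
Cy55Nh428R	CCRCCRCANACMACGTC	reverse	388	404	universal	Deslippe1		32	56.6-67.5
Ueda407R	AAICCRCCRCAIACIACRTC	reverse	388	407	universal	Ueda1		8	63.9-70.6
DVV	ATIGCRAAICCICCRCAIACIACRTC	reverse	388	413	universal	Ando1		8	71.7-75.8
MehtaR	GGCATNGCRAANCCVCCRCANAC	reverse	394	416	universal	Mehta1		768	63.2-75.1
VCG	ATIGGCATIGCRAAICCICCRCAIAC	reverse	394	419	universal	Ando1		4	73.9-76.7
nifHRc	TGGGCYTTGTTYTCRCGGATYGGCAT	reverse	412	437	universal	Rsch1		16	69.1-74.2
nifHRb	TGSGCYTTGTCYTCRCGGATBGGCAT	reverse	412	437	universal	Rsch1	probable_sequence_error	48	70.0-76.0
PicenoR436	SACGATGTAGATPTCCTG	reverse	436	453	universal	Piceno1	nonstandard_bases	4	
R6	TCIGGIGARATGATGGC	reverse	457	473	universal	Marusina1		2	61.1-62.5
polR	ATSGCCATCATYTCRCCGGA	reverse	457	476	universal	Poly1		8	63.7-67.5
nifH1	ADNGCCATCATYTCNCC	reverse	460	476	universal	Zehr2		96	52.5-63.9
nifH22	ADWGCCATCATYTCRCC	reverse	460	476	universal	Yeager1		24	53.2-60.9
nifH2-ZANI	ANDGCCATCATYTCNCC	reverse	460	476	universal	Zani1	renamed;linker_removed	96	52.5-63.6
470	TANANNGCCATCATYTCNCC	reverse	460	479	universal	Poly1		512	53.8-65.7
nifH-univ-463r	GCRTAIABNGCCATCATYTC	reverse	463	482	universal	Widmer1		48	55.7-63.8
Emino	GCRTAIAIIGCCATCATYTC	reverse	463	482	universal	Poly1		4	60.2-63.4
nifHR-2	ATGATGGCSATGTAYGCSGCSAACAA	forward	466	491	universal	Rsch1	printed_sense_strand;linker_removed	16	70.0-71.7
nifHR	TTGTTSGCSGCRTACATSGCCATCAT	reverse	466	491	universal	Rsch2		16	70.0-71.7
nifH-3r	TTGTTGGCIGCRTASAKIGCCAT	reverse	469	491	universal	Fedorov1		8	68.5-72.1
nifH3	ATRTTRTTNGCNGCRTA	reverse	478	494	universal	Zani1	window_printed_494-478	128	46.1-61.5
YAA-poly	YAAATRTTRTTNGCNGCRTA	reverse	478	497	universal	Poly1	probable_sequence_error;linker_removed	256	49.5-63.5
RL25	CAGATCAGVCCGCCSAGRCGMAC	reverse	532	554	universal	Bagwell1		24	67.5-74.1
primer-r	GGCACGAAGTGGATCAGCTG	reverse	619	638	universal	FloresMireles1		1	64.3
AMR-R	GCTACTACYTCGCCSGA	reverse			universal	Rsch2	does_not_match_nifH		
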