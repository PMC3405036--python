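pair_name	fwd_name	rev_name	pos_start	pos_end	length	flagged
Nh21F/Cy55Nh428R	Nh21F	Cy55Nh428R	19	404	386	
Ueda19F/407R	Ueda19F	Ueda407R	19	407	389	
NH21F/nifH1	Nh21F	nifH1	19	476	458	
nifH19F/nifH-univ463R	nifH19F	nifH-univ-463r	19	482	464	
Ueda19F/nifH-univ463r	Ueda19F	nifH-univ-463r	19	482	464	
19F/nifH3	nifH19F	nifH3	19	494	476	fwd_name_ambiguous_resolved_by_coordinates
Nh21F/nifH3	Nh21F	nifH3	19	494	476	
nifH3/nifH4	nifH4	nifH3	22	494	473	
Primer-f/Primer-r	primer-f	primer-r	23	638	616	
FGPH19/FGPH273	FGPH19	FGPH273'	25	279	255	
PicenoF44/PicenoR436	PicenoF44	PicenoR436	25	453	429	nonstandard_bases
F1/R6	F1	R6	25	473	449	
FGPH19/PolR	FGPH19	polR	25	476	452	
F1/nifH3r	F1	nifH-3r	25	491	467	
MehtaF/MehtaR	MehtaF	MehtaR	28	416	389	
IGK/FGPH273'	IGK	FGPH273'	31	279	249	
IGK/DVV	IGK	DVV	31	413	383	
IGK/VCG	IGK	VCG	31	419	389	
nifHF/nifHRb	nifHF-Rösch	nifHRb	31	437	407	fwd_name_resolved_by_coordinates
nifHF/nifHRc	nifHF-Rösch	nifHRc	31	437	407	fwd_name_resolved_by_coordinates
IGK/primer-4=AQE	IGK	primer-4=AQE	31	453	423	
IGK/PolR	IGK	polR	31	476	446	
nifHF-Rösch/nifHR	nifHF-Rösch	nifHR	31	491	461	
IGK/YAA=nifH3	IGK	nifH3	31	494	464	rev_name_resolved_to_nifH3
RL28/RL25	RL28	RL25	37	554	518	
KAD3/DVV	KAD3	DVV	106	413	308	
KAD3/VCG	KAD3	VCG	106	419	314	
469/R6	469	R6	112	473	362	
469/nifH1	469	nifH1	112	476	365	
469/470	469	470	112	479	368	
nifHFor/470	nifH-univ-f112	470	112	479	368	fwd_name_inconsistent_resolved_by_coordinates
nif112/nifH-univ463R	nif112	nifH-univ-463r	112	482	371	
nifB/nifHRev	nifH-b1-forB	nifH-b1-rev	112	482	371	names_inconsistent_resolved_by_coordinates
PolF/primer-4=AQE	polF	primer-4=AQE	115	453	339	
F2/R6	F2	R6	115	473	359	
nifH2/R6	nifH2	R6	115	473	359	
nifH1/nifH2	nifH2	nifH1	115	476	362	
PolF/PolR	polF	polR	115	476	362	
Kadino/Emino	Kadino	Emino	115	482	368	
Kadino/nifH-univ-463R	Kadino	nifH-univ-463r	115	482	368	
nifH11/nifH22	nifH11	nifH22	118	476	359	
nifH-2f/nifH-3r	nifH-2f	nifH-3r	277	491	215	
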