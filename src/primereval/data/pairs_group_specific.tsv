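pair_name	fwd_name	rev_name	pos_start	pos_end	length	flagged
ChenBR1/ChenBR2	ChenBR1	ChenBR2	18	698	681	
nifH-a1-forA/nifH-a1-rev	nifH-a1-forA	nifH-a1-rev	19	482	464	
nifH-f1-forA/nifH-f1-rev	nifH-f1-forA	nifH-f1-rev	19	482	464	
nifHF/nifHI	nifHF	nifHI	25	806	782	
primer-3/primer-4=AQE	primer-3	primer-4=AQE	37	453	417	
nifHf1/nifH-269	nifHf1	nifH-269	43	341	299	
nifHf1/nifHr	nifHf1	nifHr	43	690	648	
Olsen1/Olsen2	Olsen1	Olsen2	106	494	389	
cyanoF/cyanoR	cyanoF	cyanoR	108	482	375	
nifH-a1-forB/nifH-a1-rev	nifH-a1-forB	nifH-a1-rev	112	482	371	
nifH-a2-forB/nifH-a2-rev	nifH-a2-forB	nifH-a2-rev	112	482	371	
nifH-b1-forB/nifH-b1-rev	nifH-b1-forB	nifH-b1-rev	112	482	371	
nifH-c1-forB/nifH-c1-rev	nifH-c1-forB	nifH-c1-rev	112	482	371	
nifH-f1-forB/nifH-f1-rev	nifH-f1-forB	nifH-f1-rev	112	482	371	
nifH-g1-forB/nifH-g1-rev	nifH-g1-forB	nifH-g1-rev	112	482	371	
nifHFor/NifHRev	nifHFor	NifHRev	136	452	317	
cylnif-F/cylnif-R	cylnif-F	cylnif-R	156	375	220	
NIFH2F/NIFH5R	NIFH2F	NIFH5R	231	326	96	
FGPH750/FGPD913'	FGPH750	FGPD913'	759	874	116	pos_end_derived_from_printed_length;beyond_reference_stop_codon
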