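# Unified nearest-neighbor duplex parameters (SantaLucia 1998).
# stack = 5'->3' dinucleotide on one strand, paired with its complement.
stack	dH_kcal	dS_cal
AA	-7.9	-22.2
AC	-8.4	-22.4
AG	-7.8	-21.0
AT	-7.2	-20.4
CA	-8.5	-22.7
CC	-8.0	-19.9
CG	-10.6	-27.2
CT	-7.8	-21.0
GA	-8.2	-22.2
GC	-9.8	-24.4
GG	-8.0	-19.9
GT	-8.4	-22.4
TA	-7.2	-21.3
TC	-8.2	-22.2
TG	-8.5	-22.7
TT	-7.9	-22.2
init_GC	0.1	-2.8
init_AT	2.3	4.1
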