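# Inosine-containing stack parameters: APPROXIMATION.
# Each value is the mean of the four unified stacks obtained by
# substituting A/C/G/T at the inosine position (II averages all 16).
# Swappable by config; no packaged acceptance value depends on it.
stack	dH_kcal	dS_cal
AI	-7.825	-21.5
IA	-7.95	-22.1
CI	-8.725	-22.7
IC	-8.6	-22.225
GI	-8.6	-22.225
IG	-8.725	-22.7
TI	-7.95	-22.1
IT	-7.825	-21.5
II	-8.275	-22.131
init_I	1.2	0.65
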