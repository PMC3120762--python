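locus	scenario	k	LnL	AIC
coi	full model	9	21.6	-25.2
coi	S>A, S>F	5	-6.0	22.0
coi	F>S, F>A	5	-63.9	137.9
coi	A>F, A>S	5	-37.7	85.4
coi	F>S>A	5	-6.0	22.0
coi	A>S>F	5	-64.0	138.0
coi	S>F>A	5	-63.9	137.9
coi	A>F>S	5	-37.7	85.4
coi	S>A>F	5	21.6	-33.2
coi	F>A>S	5	-55.6	121.2
hsp70	full model	9	194.88	-371.76
hsp70	S>A, S>F	5	-44.58	99.15
hsp70	F>S, F>A	5	-318.35	646.70
hsp70	A>F, A>S	5	-74.56	159.12
hsp70	F>S>A	5	-74.56	159.12
hsp70	A>S>F	5	-314.03	638.06
hsp70	S>F>A	5	-290.15	590.30
hsp70	A>F>S	5	-71.33	152.66
hsp70	S>A>F	5	194.89	-379.79
hsp70	F>A>S	5	-318.35	646.70
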