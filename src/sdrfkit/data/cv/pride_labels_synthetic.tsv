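# Synthetic label snapshot: channel names in the PRIDE namespace pattern.
# The label NAMES are the standard TMT/SILAC channel names; the numeric
# accession ids here are placeholders, not verified PRIDE CV ids.
PRIDE:0100126	TMT126	PRIDE
PRIDE:0100127	TMT127	PRIDE
PRIDE:0100128	TMT127N	PRIDE
PRIDE:0100129	TMT127C	PRIDE
PRIDE:0100130	TMT128	PRIDE
PRIDE:0100131	TMT128N	PRIDE
PRIDE:0100132	TMT128C	PRIDE
PRIDE:0100133	TMT129	PRIDE
PRIDE:0100134	TMT129N	PRIDE
PRIDE:0100135	TMT129C	PRIDE
PRIDE:0100136	TMT130	PRIDE
PRIDE:0100137	TMT130N	PRIDE
PRIDE:0100138	TMT130C	PRIDE
PRIDE:0100139	TMT131	PRIDE
PRIDE:0100140	TMT131C	PRIDE
PRIDE:0100141	TMT132N	PRIDE
PRIDE:0100142	TMT132C	PRIDE
PRIDE:0100143	TMT133N	PRIDE
PRIDE:0100144	TMT133C	PRIDE
PRIDE:0100145	TMT134N	PRIDE
PRIDE:0100146	SILAC light	PRIDE
PRIDE:0100147	SILAC medium	PRIDE
PRIDE:0100148	SILAC heavy	PRIDE
PRIDE:0100149	label free sample	PRIDE
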