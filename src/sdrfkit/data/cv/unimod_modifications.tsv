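# UNIMOD snapshot — common search modifications
UNIMOD:1	Acetyl	UNIMOD
UNIMOD:4	Carbamidomethyl	UNIMOD
UNIMOD:5	Carbamyl	UNIMOD
UNIMOD:7	Deamidated	UNIMOD
UNIMOD:21	Phospho	UNIMOD
UNIMOD:27	Glu->pyro-Glu	UNIMOD
UNIMOD:28	Gln->pyro-Glu	UNIMOD
UNIMOD:34	Methyl	UNIMOD
UNIMOD:35	Oxidation	UNIMOD
UNIMOD:36	Dimethyl	UNIMOD
UNIMOD:37	Trimethyl	UNIMOD
UNIMOD:121	GG	UNIMOD
UNIMOD:188	Label:13C(6)	UNIMOD
UNIMOD:259	Label:13C(6)15N(2)	UNIMOD
UNIMOD:267	Label:13C(6)15N(4)	UNIMOD
UNIMOD:214	iTRAQ4plex	UNIMOD
UNIMOD:730	iTRAQ8plex	UNIMOD
UNIMOD:737	TMT6plex	UNIMOD
UNIMOD:2016	TMTpro	UNIMOD
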