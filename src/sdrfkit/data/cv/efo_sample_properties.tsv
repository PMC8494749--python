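# EFO/UBERON/PATO/MONDO snapshot — organism parts, phenotypes, diseases, cell lines
UBERON:0002107	liver	UBERON
UBERON:0000955	brain	UBERON
UBERON:0002048	lung	UBERON
UBERON:0000948	heart	UBERON
UBERON:0002113	kidney	UBERON
UBERON:0000178	blood	UBERON
UBERON:0002371	bone marrow	UBERON
UBERON:0002097	skin of body	UBERON
UBERON:0002106	spleen	UBERON
UBERON:0001264	pancreas	UBERON
UBERON:0002367	prostate gland	UBERON
UBERON:0000310	breast	UBERON
UBERON:0000468	multicellular organism	UBERON
UBERON:0001155	colon	UBERON
PATO:0000461	normal	PATO
PATO:0000383	female	PATO
PATO:0000384	male	PATO
MONDO:0004992	cancer	MONDO
MONDO:0005148	type 2 diabetes mellitus	MONDO
MONDO:0007254	breast cancer	MONDO
MONDO:0005061	lung adenocarcinoma	MONDO
EFO:0001185	HeLa	EFO
EFO:0001187	HEK293	EFO
EFO:0001203	MCF-7	EFO
EFO:0001086	A549	EFO
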