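# PSI-MS snapshot — instrument models and cleavage agents
MS:1000449	LTQ Orbitrap	MS
MS:1001742	LTQ Orbitrap Velos	MS
MS:1001911	Q Exactive	MS
MS:1002634	Q Exactive Plus	MS
MS:1002523	Q Exactive HF	MS
MS:1002877	Q Exactive HF-X	MS
MS:1002416	Orbitrap Fusion	MS
MS:1002732	Orbitrap Fusion Lumos	MS
MS:1003029	Orbitrap Exploris 480	MS
MS:1003005	timsTOF Pro	MS
MS:1000932	TripleTOF 5600	MS
MS:1001251	Trypsin	MS
MS:1001313	Trypsin/P	MS
MS:1001309	Lys-C	MS
MS:1001303	Arg-C	MS
MS:1001304	Asp-N	MS
MS:1001306	Chymotrypsin	MS
MS:1001956	unspecific cleavage	MS
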