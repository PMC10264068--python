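nuclease_name	source_organism	isotype	anticodon	cleavage_bond	motif	modification_dependent	citation_note
VapC	Mycobacterium smegmatis MC2-155 / M. tuberculosis H37Rv	Ser	gga	anticodon	GA	0	serine isoacceptor cleaved at the GA dinucleotide inside the anticodon
VapC	Mycobacterium smegmatis MC2-155 / M. tuberculosis H37Rv	Ser	tga	anticodon	GA	0	serine isoacceptor cleaved at the GA dinucleotide inside the anticodon
VapC	Mycobacterium smegmatis MC2-155 / M. tuberculosis H37Rv	Ser	cga	anticodon	GA	0	serine isoacceptor cleaved at the GA dinucleotide inside the anticodon
VapC	Mycobacterium smegmatis MC2-155 / M. tuberculosis H37Rv	Ser	aga	anticodon	GA	0	serine isoacceptor cleaved at the GA dinucleotide inside the anticodon
RelE	Mycobacterium	Sup	cta	anticodon	-	0	stop-codon-reading (suppressor) anticodon listed among avoided RelE targets
RelE	Mycobacterium	Leu	tta	anticodon	-	0	leucine isoacceptor listed among avoided RelE targets
RelE	Mycobacterium	Gln	cga	anticodon	-	0	transcribed as published; note the anticodon cga would not decode a glutamine codon
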