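nuclease_name	source_organism	isotype	anticodon	cleavage_bond	motif	modification_dependent	citation_note
VapC-LT2	Shigella flexneri / Salmonella enterica	fMet	cat	anticodon	-	0	initiator tRNA cleaved within the anticodon; target generally avoided by phages
PrrC	Escherichia coli	Lys	ttt	anticodon	-	0	cleaved on phage sensing; coliphage T4 carries a ligase (rnl1/rnl2) that repairs the cut
Colicin D	Escherichia coli	Arg	*	5	-	0	all arginine isoacceptors; characterized cut lies on the 3' side of the anticodon loop, recorded here at the loop-edge bond
Colicin E5	Escherichia coli	Tyr	gta	anticodon	-	1	cleavage requires the modified wobble position
Colicin E5	Escherichia coli	His	gtg	anticodon	-	1	cleavage requires the modified wobble position
Colicin E5	Escherichia coli	Asn	gtt	anticodon	-	1	cleavage requires the modified wobble position
Colicin E5	Escherichia coli	Asp	gtc	anticodon	-	1	cleavage requires the modified wobble position
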