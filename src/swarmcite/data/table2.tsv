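protein	A	B	C	D	E	F	G	H	I	J	K
AKT1	x	x	x	x	x	x	x	x	x	x	x
ATG5	x	x	x	x	x	x	x		x		x
AXL	x	x	x								x
CDK4	x		x		x	x		x			x
CTNNB1	x		x		x	x	x	x		x	x
CYCS	x	x	x		x	x	x				x
CYP27B1/VDR	x		x							x	
DDAH1	x		x								
DDAH2	x		x								
DNMT3A	x		x		x	x		x			x
DNMT3B	x		x		x	x		x			x
DRD4	x		x								
GRB2	x		x		x	x	x	x	x	x	x
GSN	x		x								x
HDAC2	x		x		x	x	x	x			x
MAPK1	x		x		x	x	x	x	x		x
MTOR	x		x	x	x	x	x	x	x		x
NOTCH1	x		x		x	x	x			x	x
NRP1	x		x		x			x			x
NT5E	x	x	x								x
PTEN	x	x	x	x	x	x	x		x	x	x
REST	x		x								
SMAD3	x		x		x	x	x	x		x	x
SOD1	x		x			x	x			x	x
SOD2	x		x			x					x
TGFB1	x		x		x	x	x			x	x
TNFRSF1A	x	x	x		x	x	x	x		x	x
TNFSF10	x	x	x						x		x
TNFSF11	x		x		x	x		x	x		x
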