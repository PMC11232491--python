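protein	A	B	C	D	E	F	G	H	I	J	K
ABCA1	x	x	x		x	x			x	x	x
AKT1	x	x	x		x	x	x	x	x	x	x
BAIAP2			x								x
CASP8	x	x	x			x	x		x	x	x
DLG4	x		x			x		x			x
FGF2	x	x	x			x	x	x	x	x	x
FZD2	x										x
MDM2	x		x			x	x	x		x	x
MERTK	x	x	x		x	x		x	x		x
MMP14	x		x			x	x	x	x	x	x
PDIA3			x				x				x
PRKCA	x		x		x	x	x		x	x	x
RAC1	x	x	x			x					x
RPS6KB1	x	x	x			x	x		x	x	x
SRF	x		x			x					x
TGFA	x		x		x	x	x		x		x
THBS1	x	x	x		x	x	x	x	x		x
TIAM1	x		x			x					x
VTN	x	x	x			x			x		x
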