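protein	A	B	C	D	E	F	G	H	I	J	K
AGER	x	x	x		x	x	x		x		x
AGTR1	x		x		x	x	x		x		
APOA1	x	x	x		x		x		x	x	
BECN1	x	x	x	x	x	x	x		x		x
BMP2	x		x		x	x				x	
CAPN1	x		x				x				x
CASP8	x	x	x		x	x	x		x		x
CAV1	x		x		x	x			x	x	x
CCL5	x	x	x	x	x	x	x		x	x	x
CD40	x	x	x		x		x		x		x
CD58	x				x				x		x
CD86	x	x	x		x	x			x		x
CFL1	x		x						x		x
CYP27B1	x					x				x	
EDN1	x		x		x	x	x		x	x	x
FGF1	x		x		x		x				x
FOXO3	x		x		x	x	x	x	x	x	x
GRB2	x		x		x				x	x	x
IGF1	x	x	x		x	x	x	x	x		x
IKBKB	x	x	x		x	x	x		x		x
IL18	x	x	x	x	x	x	x	x	x	x	x
IL1B	x	x	x	x	x	x	x	x	x	x	x
IL1RN	x		x		x	x	x		x		
IL2RA	x		x		x	x	x	x	x		
IL33	x	x	x	x	x	x	x	x	x		x
ITGB3	x	x	x		x	x			x		x
LTA	x	x			x				x		x
NFKB1	x	x	x	x		x	x		x	x	x
PDIA3	x		x		x	x	x		x		
PPARG	x	x	x		x	x	x	x	x	x	x
RBP4	x		x								
RELA	x	x	x		x	x	x	x	x	x	x
RIPK1	x	x	x		x	x	x	x	x		x
S100A9	x		x						x		
S1PR3	x				x						
SAG	x		x				x		x		
SELE	x		x		x	x	x		x	x	x
SELP	x	x	x		x	x	x		x		x
SERPINC1	x		x		x	x	x		x		
SERPINE1	x		x					x	x	x	x
SLIT2	x					x					
SREBF2	x	x	x		x		x		x		
TGFB1	x	x	x	x	x	x	x	x	x	x	x
TGFBR1	x		x		x	x			x	x	x
TIMP2	x		x		x	x	x		x		x
TNF	x	x	x	x	x	x	x	x	x	x	x
TNFAIP3	x		x		x	x		x	x		
TRAF6	x	x	x	x	x	x	x	x	x	x	x
VAV1	x	x	x				x	x			
ZNF580	x										
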