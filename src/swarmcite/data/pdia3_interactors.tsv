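protein_a	protein_b
PDIA3	AKT1
PDIA3	BAIAP2
PDIA3	ENO1
PDIA3	GAPDH
PDIA3	GSK3B
PDIA3	MTOR
PDIA3	NFKB1
PDIA3	PCBP2
PDIA3	PCBP2
PDIA3	PDIA3
PDIA3	PPARG
PDIA3	SOD1
PDIA3	STAT3
PDIA3	TGFB1
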