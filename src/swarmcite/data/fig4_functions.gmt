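atherosclerosis	all proteins listed in the printed overlap grid	AKT1	ATG5	AXL	CDK4	CTNNB1	CYCS	CYP27B1/VDR	DDAH1	DDAH2	DNMT3A	DNMT3B	DRD4	GRB2	GSN	HDAC2	MAPK1	MTOR	NOTCH1	NRP1	NT5E	PTEN	REST	SMAD3	SOD1	SOD2	TGFB1	TNFRSF1A	TNFSF10	TNFSF11
macrophage polarization	green nodes of the figure network (grid column E)	AKT1	ATG5	CDK4	CTNNB1	CYCS	DNMT3A	DNMT3B	GRB2	HDAC2	MAPK1	MTOR	NOTCH1	NRP1	PTEN	SMAD3	TGFB1	TNFRSF1A	TNFSF11
macrophage autophagy	red nodes of the figure network; the printed grid column D additionally marks MTOR	AKT1	ATG5	PTEN
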