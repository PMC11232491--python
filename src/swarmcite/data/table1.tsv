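94–98	342–348	422–433	580–596	702–709	726–730	731–745	746–779	780–788	789–795	1,055–1,061	1,255–1,264	1,519–602	1,795–1,806	1,985–1,990	2,128–2,137	2,349–2,357	2,928–2,936	2,946–3,049	3,096–3,143	3,401–3,470	3,620–3,633	3,648–3,663	3,766–3,775	4,041–4,061	4,460–4,495	5,106–5,116	6,008–6,017	7,116–7,158
BMP7	ACTN3	C1S	AKT1	AGT	CYP27B1	BECN1	AGTR1	AGER	CFHR5	CYP24A1	AKT1	ABCG1	CFLAR	AKT1	CDK6	AKT1	AGT	AGER	AKT1	AKT1	ABCA1	ACTN3	ALDOB	ARNTL	AKAP8	AKT1	CAT	AKT1
CYP24A1	ADRBK1	C3	CYCS	AKT1	ITGB3	BMP2	APOA1	APOA1	IL18	CYP27B1	ATG5	ACACA	EMD	CTNNB1	CFLAR	CAV1	AKT1	AGT	AXL	APCS	AKT1	AKT1	ATG5	CSF2	ARG1	ARNTL	CYP27B1	AXL
DRD1	C1QTNF1	C4B	CYP27B1	APOA1	NFKB1	CAV1	CFL1	BECN1	IL1A	DHCR24	CAMP	AGER	INSR	EDN3	CYP27B1	CFLAR	CCL21	AKT1	BCL2L1	ARNTL	BAIAP2	BECN1	CTSD	CYP24A1	BMP4	ATG5	DHCR24	CAD
DRD5	CAV1	CYP27B1	DRD3	ARNTL	PPARG	CCL5	CYP27B1	CAPN1	IL1B	LBR	CYP27B1	ALOX15	MAPK1	GRB2	MAPK1	CYP27B1	CX3CR1	APCS	BCL2L11	ATG5	C2	CCL5	ENO1	CYP27B1	CAPN1	CDK6	DNMT3A	CAT
F5	CYBA	FCN2	DRD4	BMP2	SREBF2	CD58	FGF1	CASP8	IL6	TM7SF2	DHCR24	ALOX15B	PDIA3	MET	NOTCH1	DDAH1	CYP24A1	ARNTL	BTRC	AXL	CASP8	CCR3	G6PC	DRD1	CREB1	CFLAR	DNMT3B	CDK4
ITGB3	CYP27B1	FCN3	FGB	CALR	TGFBR1	CYP27B1	GPLD1	CD40	IL6R	VDR	IRS1	ANGPTL4	SMAD2	NOTCH1	PTPN1	DDAH2	CYP27B1	ATG5	CASP7	BMP7	DLG4	CFL1	GAPDH	DRD3	CREBBP	CYBB	DRD3	CFLAR
SOD1	DNM2	KRT1	GLUL	CCL5	TNF	EDN1	IKBKB	CD86	IRAK2		LBR	APOA1	SMAD3	NRP1	SMAD2	DNMT3B	EPCAM	BECN1	CASP8	BMPR1A	FGF2	CTF1	LIPG	DRD4	CTSD	DRD1	ECH1	CLDN1
SOD2	EDN1	LY96	HDAC2	CYP27B1		FCN1	IL18	GRB2	LTA		MAPK1	ARNTL	TGFB1	PLA2G7	SMAD3	MAPK1	EPO	BMP2	CDK6	CD40	FZD2	CTSD	PCBP1	DRD5	FGF13	DRD3	EDN3	DDAH1
TGFB1	EDN2	MYD88	IRS1	INS		FGF1	IL1B	IKBKB	NOS3		MTOR	ATF4		SMAD3	TCF21	NOTCH1	HHEX	BMP7	CDKN1A	CD47	MDM2	EDN1	PCBP2	GC	FOXO3	DRD4	IGF2	DDAH2
VDR	IL1B	POU2F2	NOTCH1	NFKB1		FOXO3	IL1RN	IL33	OSMR		NOTCH1	BAIAP3		SOD2	TCF7	PROC	IDO1	BMPR1A	CFLAR	CDH2	MERTK	EDN2	PDIA3	GLUL	FYN	GLUL	INSR	DNMT3A
	KCNA1	RPS6KB1	PRKCE	S100A9		IGF1	IL2RA	NFKB1	TNF		PALM	BMP2		TCF21	TNFRSF1A	TNFRSF1A	IGF1R	CANX	CTSD	CDK4	MMP14	HAMP	PKM	IDO1	FZD1	HRAS	LBR	DNMT3B
	KCNIP1	TNFRSF13C	RAN	TNF		IL1B	IL33	PDIA3			PC	BTRC		VDR		VDR	IGF2	CASP7	CYP27B1	CDK6	NLGN1	HDAC1		IDO2	GLI3	MAX	TM7SF2	DRD4
	NOS3	TNFSF13B	REST	TXNIP		NFKB1	KRT10	PPARG			PLG	C1QTNF3				ZEB2	MAPK1	CAST	DDAH1	CFLAR	PDIA3	HPCA		IL23A	GREM1	MTOR	UBC	FLT3
	PRKG1	VSIG4	SMAD3			PDIA3	LTA	RBP4			PTEN	CAPN3					MTOR	CCL21	DDAH2	CYBB	PRKCA	IL18		MLLT4	GSK3B	NEDD4l		GLUL
	SERPINE1		SOD1			RIPK1	NCOA3	RELA			PTS	CARKD					PLAU	CCR7	DFFA	CYP24A1	RAC1	IL1A		MSN	HES1	PDIA3		GSN
			TM7SF2			S100A9	NFKB1	RIPK1			REST	CAV1					PTK2B	CD1C	DHCR24	CYP27B1	RPS6KB1	IL1B		NPS	IL7	PTEN		HDAC2
			TNFRSF1A			SERPINE1	PDIA3	TGFB1			SPR	CCL5					SMAD3	CD1D	DNMT1	DNMT1	SRF	IL1RN		PC	MAPK14	SOD1		MAPK1
			TNFSF10			SLIT2	S1PR3	TNF			TM7SF2	CSF3					SMAD7	CDC42	DNMT3l	DNMT3A	TGFA	IL6		RAG1	MMP15	TGFB1		NOTCH1
			VDR			SREBF2	SAG	TRAF6				CYP27B1					TGFB1	CDK1	DRD3	DRD1	THBS1	IL6R		RAP1B	MMP26	TLR2		NT5C
						TNF	SELE	VAV1				DDIT3					THPO	CDK4	DRD4	DRD3	TIAM1	JUN		VDR	NFATC4			NT5E
						ZNF580	SELP					DRD3					TNFSF4	CDK6	EDN1	DRD4	VTN	MAPK1			NOG			NT5M
							SERPINC1					DVL1						CDKN2A	FGF1	DRD5		MCOLN3			PDIA3			PROC
							SOSTDC1					ECD						CFL1	GRB2	EDN3		MKKS			PIN1			RAN
							TIMP2					EDN1						CFLAR	IGF1	FLT1		PDIA3			PPP1CC			REST
							TNF					EDN3						CREB1	IGF2	FRS2		PTK2B			PRKCH			SDS
							TNFAIP3					ETS1						CTNNB1	IL2RA	GPR124		RELA			PTGER2			SMAD3
							TRAF6					F7						CYP27B1	INSR	GSN		RPS6KB1			PTGER4			SOD1
												FABP1						DHCR24	MAP2K1	HDAC2		STAT3			PTK2B			TGFB1
												FADS1						DNMT1	MAPK1	IDO1					WNT2			TJP2
												FAM132B						DRD3	MCOLN3	INSR					WNT3			TNFRSF11A
												FASN						E2F1	MT-CYB	MAPK1					WNT9B			TNFSF11
												FGF2						EDN1	NEDD4l	NEDD4l								VDR
												FOXA1						EIF4EBP1	NFKB1	NF2								
												FOXO3						ELAVL1	OCLN	NOTCH1								
												FYN						EZH2	PARN	PALM								
												FZD6						F3	PDIA3	PCBP4								
												GCM2						FGF1	PPARG	PDIA3								
												GFI1						FLT1	PTK2B	PLAT								
												GPX1						FRS2	PTPN6	PLCB2								
												GRB10						FSCN1	RAG1	PLG								
												GRB14						FUT7	RIPK1	PROC								
												HAND1						FYN	RPS6KB1	PTEN								
												HCLS1						GLUL	SMAD2	PTPN1								
												HDAC1						GPR29	SOD2	PTS								
												HEY1						GRB2	SREBF2	RAG1								
												HEY2						GSN	TANK	SMAD2								
												ID1						HDAC2	TNFRSF1A	SMAD3								
												IGF1						HRAS	TNFSF10	SOD2								
												IGF2						HSPB8	TRAF6	TACSTD2								
												INSR						IGF1		TGFB1								
												IRS1						IGF2		TGFBR1								
												KLF4						IL23A		TLR2								
												KNG1						INS		TNFSF10								
												L3MBTL1						INSR		TNFSF4								
												LAMP2						IRS1		VDR								
												MAPK7						ITGB3		ZEB2								
												MTA1						KL										
												NAMPT						MDM2										
												NCOA2						MTOR										
												NFKB1						MYD88										
												NME1						MYLK										
												NR1D1						NOTCH1										
												NR1D2						PARN										
												NR1H3						PDIA3										
												PDK2						PIK3CA										
												PDPK1						PPARG										
												PER2						PTK2B										
												PIAS2						PTPN1										
												PIP4K2A						PTPN6										
												PPARA						RAG2										
												PPARG						RELA										
												PPARGC1A						RELB										
												PRDM16						RIPK1										
												PRKAB2						RPS6KB										
												PRKCA						RPS6KB1										
												PRKCE						S100A9										
												PTPRJ						SERPINE1										
												RORA						SLIT2										
												RPS6KB1						SMAD2										
												S100A8						SMAD3										
												S100A9						SOD2										
												SERPINA4						TCF7										
												SIRT1						TGFB1										
												SLC27A5						TGFBR1										
												SLIT2						TLR2										
												SPI1						TLR3										
												SREBF1						TNFRSF1A										
												SREBF2						TNFSF11										
												STUB1						TNFSF4										
												THBS1						TRAF6										
												TIAM1						TSC1										
												TNFAIP6						UBC										
												WLS						VDR										
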