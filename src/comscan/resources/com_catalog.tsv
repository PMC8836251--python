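# Curated Arabidopsis thaliana chloroplast outer membrane (COM) proteome:
# 138 loci with literature-assigned targeting-pathway topology category,
# predicted N-terminal transit peptide (n_tp) and C-terminal reverse
# TP-like (c_tp_like) flags, a marker for proteins added beyond the
# Inoue (2015) list of 117, and functional category where assigned.
agi	name	topology_category	n_tp	c_tp_like	newly_identified	functional_category
At1g67690	M3 Protease	SA	0	1	0	unassigned
At2g19860	HXK2	SA	0	0	0	unassigned
At2g34585	-	SA	0	0	1	unknown
At2g38670	PECT1	SA	0	0	0	unassigned
At3g17970	TOC64-III	SA	0	1	0	unassigned
At3g21865	PEX22	SA	0	1	0	unassigned
At3g52420	OEP7	SA	0	0	0	unassigned
At3g63170	FAP1	SA	1	0	0	unassigned
At4g12470	pEARLI1-Like Lipid Transfer Protein	SA	1	0	1	lipid metabolism
At4g27680	NTPase	SA	0	0	0	unassigned
At4g29130	HXK1	SA	0	0	0	unassigned
At5g17770	CBR	SA	0	0	0	unassigned
At5g20520	WAV2	SA	0	1	0	unassigned
At5g25900	KO1/GA3	SA	0	0	0	unassigned
At5g51020	CRL	SA	0	0	0	unassigned
At5g64816	-	SA	0	1	0	unassigned
At1g02280	TOC33	TA	0	0	0	unassigned
At1g09920	-	TA	0	0	0	unassigned
At1g13900	PAP2	TA	0	0	0	unassigned
At1g26340	Cytochrome b5	TA	0	0	1	other metabolism and regulation
At1g27300	-	TA	0	0	0	unassigned
At1g27390	Tom20-2	TA	0	0	0	unassigned
At2g16070	PDV2	TA	0	0	0	unassigned
At2g32240	DUF869	TA	0	0	0	unassigned
At3g03870	F20H23.8 Protein	TA	0	1	1	unknown
At3g27820	MDAR4	TA	0	0	0	unassigned
At3g57090	Mitochondrial Fission 1 Protein	TA	0	0	1	organellar fission
At3g63150	MIRO2	TA	0	0	0	unassigned
At4g32250	Tyrosine Kinase	TA	0	0	0	unassigned
At4g35000	APX3	TA	0	0	0	unassigned
At5g05000	TOC34	TA	0	1	0	unassigned
At5g11560	-	TA	0	1	0	unassigned
At5g21990	OEP61-TPR	TA	0	0	0	unassigned
At5g27330	-	TA	0	0	0	unassigned
At5g27540	MIRO1	TA	0	0	0	unassigned
At5g56730	Peptidase M16	TA	0	0	0	unassigned
At1g16000	OEP9	OTHER_SINGLE_PASS	0	0	0	unassigned
At1g80890	OEP9.2	OTHER_SINGLE_PASS	0	0	0	unassigned
At2g25660	TIC236	OTHER_SINGLE_PASS	1	1	1	protein import
At3g52230	OMP24 Homolog	OTHER_SINGLE_PASS	0	0	0	unassigned
At3g63160	OEP6	OTHER_SINGLE_PASS	0	0	0	unassigned
At1g12230	Transaldolase	MULTI_PASS	1	0	0	unassigned
At1g34430	PDC E2	MULTI_PASS	1	0	0	unassigned
At1g44170	ALDH3H1	MULTI_PASS	0	1	0	unassigned
At1g54150	E3 Ubiquitin-Protein Ligase SPL2	MULTI_PASS	0	1	1	protein turnover and modification
At1g59560	E3 Ubiquitin-Protein Ligase SPL1	MULTI_PASS	0	0	1	protein turnover and modification
At1g63900	SP1	MULTI_PASS	0	1	0	unassigned
At1g64850	-	MULTI_PASS	0	1	0	unassigned
At1g68680	-	MULTI_PASS	0	0	0	unassigned
At1g77590	LACS9	MULTI_PASS	0	1	0	unassigned
At2g01320	WBC7	MULTI_PASS	0	0	0	unassigned
At2g11810	MGD3	MULTI_PASS	0	1	0	unassigned
At2g28900	OEP16-1	MULTI_PASS	0	0	0	unassigned
At2g34590	PDC E1 Beta	MULTI_PASS	1	0	0	unassigned
At2g40690	G3P Dehydrogenase	MULTI_PASS	1	0	1	lipid metabolism
At2g44640	-	MULTI_PASS	0	0	0	unassigned
At2g47770	TSPO	MULTI_PASS	0	0	0	unassigned
At3g07430	YlmG Homolog	MULTI_PASS	1	0	1	organellar fission
At3g49560	TIM Protein	MULTI_PASS	0	0	1	protein import
At3g51870	PAPST1 Homolog	MULTI_PASS	0	0	0	unassigned
At3g62880	OEP16-4	MULTI_PASS	0	0	0	unassigned
At4g15440	HPL Homolog	MULTI_PASS	0	0	0	unassigned
At4g15810	NTPase	MULTI_PASS	0	0	0	unassigned
At4g16160	OEP16-2	MULTI_PASS	0	1	0	unassigned
At4g16450	Complex I Subunit	MULTI_PASS	0	1	0	unassigned
At4g26670	TIM Protein	MULTI_PASS	0	0	1	protein import
At4g27990	YGGT-B Protein	MULTI_PASS	1	0	0	unassigned
At4g31780	MGD1	MULTI_PASS	1	0	0	unassigned
At4g38920	Vacuolar ATPase Subunit	MULTI_PASS	0	0	0	unassigned
At5g06290	Prx B	MULTI_PASS	1	0	0	unassigned
At5g13530	E3 Ubiquitin-Protein Ligase KEG	MULTI_PASS	0	0	1	protein turnover and modification
At5g16010	Dehydrogenase	MULTI_PASS	0	0	1	lipid metabolism
At5g21920	YGGT-A Protein	MULTI_PASS	0	0	0	unassigned
At5g24650	TIM Protein	MULTI_PASS	0	0	1	protein import
At5g35210	PTM	MULTI_PASS	0	0	0	unassigned
At5g55510	TIM Protein	MULTI_PASS	0	0	1	protein import
At1g20816	OEP21-1	BETA_BARREL	0	0	0	unassigned
At1g45170	OEP24-1	BETA_BARREL	0	0	0	unassigned
At1g76405	OEP21-2	BETA_BARREL	0	0	0	unassigned
At2g06010	-	BETA_BARREL	0	0	0	unassigned
At2g43950	OEP37	BETA_BARREL	1	0	0	unassigned
At3g01280	VDAC1	BETA_BARREL	0	0	0	unassigned
At3g44160	P39/OEP80 TR1	BETA_BARREL	0	0	0	unassigned
At3g46740	TOC75-III	BETA_BARREL	1	0	0	unassigned
At3g48620	P36/OEP80 TR2	BETA_BARREL	0	0	0	unassigned
At4g09080	TOC75-IV	BETA_BARREL	0	0	0	unassigned
At5g15090	VDAC3	BETA_BARREL	0	0	0	unassigned
At5g19620	OEP80/TOC75-V	BETA_BARREL	1	0	0	unassigned
At5g42960	OEP24-2	BETA_BARREL	0	0	0	unassigned
At1g02560	ClpP5	OTHER	1	0	0	unassigned
At1g07930	E-Tu	OTHER	0	0	0	unassigned
At1g09340	CRB	OTHER	0	0	0	unassigned
At1g70480	DUF220	OTHER	0	1	0	unassigned
At2g16640	TOC132	OTHER	0	1	0	unassigned
At2g17390	AKR2B	OTHER	0	1	0	unassigned
At2g17695	OEP23	OTHER	0	0	0	unassigned
At2g20890	THF1/PSB29	OTHER	1	0	0	unassigned
At2g24440	-	OTHER	0	1	0	unassigned
At2g27490	ATCOAE	OTHER	0	0	0	unassigned
At2g32290	Beta-Amylase 6	OTHER	1	0	1	carbohydrate metabolism and regulation
At2g32650	PTAC18-Like	OTHER	1	0	0	unassigned
At3g01500	Beta CA1	OTHER	1	0	0	unassigned
At3g06510	SFR2/GGGT	OTHER	0	1	0	unassigned
At3g06960	TGD4	OTHER	0	0	0	unassigned
At3g11670	DGD1	OTHER	1	0	0	unassigned
At3g12580	Hsc70-4	OTHER	0	1	0	unassigned
At3g16620	TOC120	OTHER	0	1	0	unassigned
At3g16950	PDC E3	OTHER	1	0	0	unassigned
At3g19720	ARC5	OTHER	0	0	1	organellar fission
At3g25690	CHUP1	OTHER	0	0	0	unassigned
At3g25860	PDC E2	OTHER	1	0	0	unassigned
At3g26070	PAP/FBN3a	OTHER	1	0	0	unassigned
At3g26740	CCL	OTHER	1	0	0	unassigned
At3g46030	Histone H2B	OTHER	0	1	0	unassigned
At3g46780	pTAC16	OTHER	1	0	0	unassigned
At3g49350	-	OTHER	1	0	0	unassigned
At3g53560	TPR Protein	OTHER	1	0	0	unassigned
At3g63520	Carotenoid Cleaving Protein	OTHER	0	0	1	lipid metabolism
At4g00550	DGD2	OTHER	0	1	0	unassigned
At4g02482	Putative GTPase	OTHER	1	0	0	unassigned
At4g02510	TOC159	OTHER	0	1	0	unassigned
At4g05050	UBQ11	OTHER	0	0	0	unassigned
At4g13550	Putative Triglyceride Lipase	OTHER	1	0	1	lipid metabolism
At4g14430	Enoyl-CoA Isomerase	OTHER	0	1	0	unassigned
At4g17170	RAB2	OTHER	0	1	0	unassigned
At4g36650	pBrP	OTHER	0	0	0	unassigned
At5g02500	Hsc70-1	OTHER	0	1	0	unassigned
At5g02580	Argininosuccinate Lyase	OTHER	0	0	1	other metabolism and regulation
At5g16870	PTH2 Family Protein	OTHER	0	0	0	unassigned
At5g20300	TOC90	OTHER	0	1	0	unassigned
At5g20410	MGD2	OTHER	0	1	0	unassigned
At5g23190	CYP86B1	OTHER	0	1	0	unassigned
At5g35360	CAC2/BC	OTHER	1	0	0	unassigned
At5g42070	-	OTHER	1	0	0	unassigned
At5g43070	WPP1	OTHER	0	1	0	unassigned
At5g53280	PDV1	OTHER	0	0	0	unassigned
At5g58140	PHOT2	OTHER	0	1	0	unassigned
At5g59840	RAB8A-Like Protein	OTHER	0	1	0	unassigned
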