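WP_FERROPTOSIS	synthetic fixture	GPX4	ACSL4	SLC7A11	SLC3A2	TFRC	FTH1	FTL	ACSL3	LPCAT3	ALOX15	NCOA4	ATG5	ATG7	GCLC	GCLM	GSS	NFE2L2	KEAP1	HMOX1	SAT1	GLS2	DPP4	CS	ACO1	IREB2	CARS1	CHAC1	FANCD2	HSPB1	TP53	RPL8	EMC2	CISD1	SLC40A1	STEAP3	PROM2	FURIN	ZEB1	VDAC2
KEGG_OXIDATIVE_PHOSPHORYLATION	synthetic fixture	ATP6V0A4	ATP6V0A1	ATP6V1A	ATP5F1A	ATP5F1B	ATP5F1C	NDUFA1	NDUFA2	NDUFB1	NDUFS1	NDUFV1	COX4I1	COX5A	COX6A1	COX7A2	UQCRC1	UQCRC2	UQCRB	CYC1	SDHA	SDHB	PPA1	OXP001	OXP002	OXP003	OXP004	OXP005	OXP006	OXP007	OXP008	OXP009	OXP010	OXP011	OXP012	OXP013	OXP014	OXP015	OXP016	OXP017	OXP018	OXP019	OXP020	OXP021	OXP022	OXP023	OXP024	OXP025	OXP026	OXP027	OXP028	OXP029	OXP030	OXP031	OXP032	OXP033	OXP034	OXP035	OXP036	OXP037	OXP038	OXP039	OXP040	OXP041	OXP042	OXP043	OXP044	OXP045	OXP046	OXP047	OXP048	OXP049	OXP050	OXP051	OXP052	OXP053	OXP054	OXP055	OXP056	OXP057	OXP058	OXP059	OXP060	OXP061
GOBP_GLUTAMINE_METABOLIC_PROCESS	synthetic fixture	GLS	GLS2	GLUL	GLUD1	GLUD2	GOT1	GOT2	GPT	GPT2	SLC1A5	SLC7A5	SLC38A1	SLC38A2	PPAT	ASNS	GLN001	GLN002	GLN003	GLN004	GLN005	GLN006	GLN007	GLN008
LIT_PYROPTOSIS	synthetic fixture	GSDMD	GSDME	CASP1	CASP4	CASP5	NLRP3	NLRP1	NLRC4	AIM2	PYCARD	IL1B	IL18	NEK7	PYR001	PYR002	PYR003	PYR004	PYR005	PYR006	PYR007	PYR008	PYR009	PYR010	PYR011	PYR012	PYR013	PYR014	PYR015	PYR016	PYR017	PYR018	PYR019
LIT_PARAPTOSIS	synthetic fixture	IGF1R	ALIX	MAP3K5	MAPK1	MAPK3	JNK1	PAR001	PAR002	PAR003	PAR004	PAR005	PAR006
LIT_CUPROPTOSIS	synthetic fixture	FDX1	LIAS	LIPT1	DLD	DLAT	PDHA1	PDHB	MTF1	GLS	CDKN2A
PATHCARDS_FATTY_ACID_BIOSYNTHESIS	synthetic fixture	FASN	ACACA	ACACB	SCD	ELOVL6	ACLY	ACSS2	MCAT	OXSM	ELOVL1	FAB001	FAB002	FAB003	FAB004	FAB005	FAB006	FAB007	FAB008	FAB009	FAB010	FAB011	FAB012
PATHCARDS_GLUTATHIONE_SYNTHESIS	synthetic fixture	GCLC	GCLM	GSS	GGT1	GGCT	OPLAH	ANPEP	GPX1	GSR	GSH001	GSH002	GSH003	GSH004	GSH005	GSH006	GSH007
LIT_IRON_METABOLISM	synthetic fixture	CD163	SLC40A1	TFRC	FTH1	FTL	HMOX1	HAMP	HFE	SLC11A2	STEAP3	ACO1	IREB2	TF	TFR2	HP	HPX	FXN	CP	HEPH	SLC25A37	IRN001	IRN002	IRN003	IRN004	IRN005	IRN006	IRN007	IRN008	IRN009	IRN010	IRN011	IRN012	IRN013	IRN014	IRN015	IRN016	IRN017	IRN018	IRN019	IRN020	IRN021	IRN022	IRN023	IRN024	IRN025	IRN026	IRN027	IRN028	IRN029	IRN030	IRN031	IRN032	IRN033	IRN034	IRN035	IRN036	IRN037	IRN038	IRN039	IRN040	IRN041	IRN042	IRN043	IRN044	IRN045	IRN046	IRN047	IRN048	IRN049	IRN050
LIT_GLYCOLYSIS	synthetic fixture	HK1	HK2	GPI	PFKL	PFKM	PFKP	ALDOA	ALDOB	TPI1	GAPDH	PGK1	PGAM1	ENO1	ENO2	PKM	LDHA	LDHB	SLC2A1	GLY001	GLY002	GLY003	GLY004	GLY005	GLY006	GLY007	GLY008	GLY009	GLY010	GLY011
LIT_SELENIUM_METABOLISM	synthetic fixture	GPX1	GPX2	GPX3	GPX4	TXNRD1	TXNRD2	TXNRD3	DIO1	DIO2	DIO3	SELENOP	SELENOW	SELENOF	SEPHS1	SEPHS2	SELENOS	SEL001	SEL002	SEL003	SEL004	SEL005	SEL006	SEL007	SEL008	SEL009
HALLMARK_APOPTOSIS	synthetic fixture	CASP3	CASP8	CASP9	CASP7	BAX	BAK1	BCL2	BCL2L1	BID	BAD	APAF1	CYCS	FAS	FASLG	TNF	TNFRSF1A	TRADD	FADD	DIABLO	XIAP	BIRC3	PARP1	TP53	APOC001	APOC002	APOC003	APOC004	APOC005	APOC006	APOC007	APOC008	APOC009	APOU001	APOU002	APOU003	APOU004	APOU005	APOU006	APOU007	APOU008	APOU009	APOU010	APOU011	APOU012	APOU013	APOU014	APOU015	APOU016	APOU017	APOU018	APOU019	APOU020	APOU021	APOU022	APOU023	APOU024	APOU025	APOU026	APOU027	APOU028
REACTOME_APOPTOSIS	synthetic fixture	CASP3	CASP8	CASP9	CASP7	BAX	BAK1	BCL2	BCL2L1	BID	BAD	APAF1	CYCS	FAS	FASLG	TNF	TNFRSF1A	TRADD	FADD	DIABLO	XIAP	BIRC3	PARP1	TP53	APOC001	APOC002	APOC003	APOC004	APOC005	APOC006	APOC007	APOC008	APOC009	RAPU001	RAPU002	RAPU003	RAPU004	RAPU005	RAPU006	RAPU007	RAPU008	RAPU009	RAPU010	RAPU011	RAPU012	RAPU013	RAPU014	RAPU015	RAPU016	RAPU017	RAPU018	RAPU019	RAPU020	RAPU021	RAPU022	RAPU023	RAPU024	RAPU025	RAPU026	RAPU027	RAPU028	RAPU029	RAPU030	RAPU031	RAPU032	RAPU033	RAPU034	RAPU035	RAPU036	RAPU037	RAPU038
WP_AUTOPHAGY	synthetic fixture	ATG3	ATG4B	ATG5	ATG7	ATG10	ATG12	ATG16L1	BECN1	MAP1LC3B	ULK1	ULK2	PIK3C3	RB1CC1	ATG101	ATG13	WIPI2	SQSTM1	GABARAP	GABARAPL1	AUTC001	AUTC002	AUTC003	AUTC004	AUTC005	AUTC006	AUTC007	AUTC008	AUTC009	AUTU001	AUTU002	AUTU003	AUTU004	AUTU005	AUTU006	AUTU007	AUTU008	AUTU009	AUTU010	AUTU011	AUTU012	AUTU013	AUTU014	AUTU015	AUTU016	AUTU017	AUTU018	AUTU019	AUTU020	AUTU021	AUTU022	AUTU023	AUTU024	AUTU025	AUTU026	AUTU027
REACTOME_AUTOPHAGY	synthetic fixture	ATG3	ATG4B	ATG5	ATG7	ATG10	ATG12	ATG16L1	BECN1	MAP1LC3B	ULK1	ULK2	PIK3C3	RB1CC1	ATG101	ATG13	WIPI2	SQSTM1	GABARAP	GABARAPL1	AUTC001	AUTC002	AUTC003	AUTC004	AUTC005	AUTC006	AUTC007	AUTC008	AUTC009	RAUU001	RAUU002	RAUU003	RAUU004	RAUU005	RAUU006	RAUU007	RAUU008	RAUU009	RAUU010	RAUU011	RAUU012	RAUU013	RAUU014	RAUU015	RAUU016	RAUU017	RAUU018	RAUU019	RAUU020	RAUU021	RAUU022	RAUU023	RAUU024	RAUU025	RAUU026	RAUU027	RAUU028	RAUU029	RAUU030	RAUU031	RAUU032
KEGG_NECROPTOSIS	synthetic fixture	RIPK1	RIPK3	MLKL	TNF	TNFRSF1A	TRADD	FADD	CASP8	CFLAR	TICAM1	TLR3	TLR4	ZBP1	PGAM5	NECC001	NECC002	NECC003	NECC004	NECC005	NECC006	NECC007	NECC008	NECU001	NECU002	NECU003	NECU004	NECU005	NECU006	NECU007	NECU008	NECU009	NECU010	NECU011	NECU012	NECU013	NECU014	NECU015	NECU016	NECU017	NECU018	NECU019	NECU020	NECU021	NECU022	NECU023	NECU024	NECU025	NECU026	NECU027	NECU028
REACTOME_REGULATED_NECROSIS	synthetic fixture	RIPK1	RIPK3	MLKL	TNF	TNFRSF1A	TRADD	FADD	CASP8	CFLAR	TICAM1	TLR3	TLR4	ZBP1	PGAM5	NECC001	NECC002	NECC003	NECC004	NECC005	NECC006	NECC007	NECC008	RNEU001	RNEU002	RNEU003	RNEU004	RNEU005	RNEU006	RNEU007	RNEU008	RNEU009	RNEU010	RNEU011	RNEU012	RNEU013	RNEU014	RNEU015	RNEU016	RNEU017	RNEU018	RNEU019	RNEU020	RNEU021	RNEU022	RNEU023
PATHCARDS_TCA_CYCLE	synthetic fixture	PC	CS	ACO2	IDH1	IDH2	IDH3A	IDH3B	OGDH	DLST	SUCLA2	SUCLG1	SUCLG2	SDHA	SDHB	SDHC	SDHD	FH	MDH1	MDH2	ACLY	DLD	PDHA1	OGDHL	TCAU001	TCAU002	TCAU003	TCAU004	TCAU005	TCAU006	TCAU007	TCAU008	TCAU009	TCAU010	TCAU011	TCAU012	TCAU013	TCAU014	TCAU015	TCAU016	TCAU017
KEGG_CITRATE_CYCLE_TCA_CYCLE	synthetic fixture	PC	CS	ACO2	IDH1	IDH2	IDH3A	IDH3B	OGDH	DLST	SUCLA2	SUCLG1	SUCLG2	SDHA	SDHB	SDHC	SDHD	FH	MDH1	MDH2	ACLY	DLD	PDHA1	OGDHL	KCCU001	KCCU002	KCCU003	KCCU004	KCCU005	KCCU006	KCCU007
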