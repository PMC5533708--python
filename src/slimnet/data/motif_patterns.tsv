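motif_id	regex	kind	anchored	binder_domain_classes
LIG_PDZ_Class_1	[ST].[VIL]$	LIG	1	PDZ
DOC_PP1_RVXF_1	[RK].{0,1}[VI][^P][FW]	DOC	0	Ser/Thr phosphatase
DEG_SCF_TRCP1_1	D[ST]G.{2}[ST]	DEG	0	F-box
DEG_Nend_Nbox_1	^M{0,1}[FYLIW]	DEG	0	F-box
LIG_14-3-3_2	R.{1,2}[ST].P	LIG	0	14-3-3
LIG_14-3-3_3	[RHK][STALV].[ST].{0,2}$	LIG	1	14-3-3
LIG_EVH1_1	[FYWL]P.[FYWL]P	LIG	0	WH1/EVH1
TRG_NES_CRM1_1	[DE].{0,1}[LIM].{2,3}[LIVFM].{2,3}[LVIM].[LIV]	TRG	0	Importin_N-term
MOD_LATS_1	H.[RK].{2}[ST]	MOD	0	AGC-kinase C-terminal
LIG_NRBOX	[^P]L[^P][^P]LL[^P]	LIG	0	NHR ligand binding
MOD_NEK2_1	[FLM][^P][^P][ST][^DEP][^DE]	MOD	0	
MOD_CDK_1	[ST]P.[KR]	MOD	0	
MOD_GSK3_1	[ST].{3}[ST]	MOD	0	
MOD_CK1_1	S.{2}[ST]	MOD	0	
DOC_MAPK_gen_1	[KR].{0,2}[KR].{2,4}[ILVM].[ILVF]	DOC	0	
DOC_WW_Pin1_4	[ST]P.	DOC	0	WW domain
DOC_CYCLIN_1	[RK].L.{0,1}[FYLIVMP]	DOC	0	
LIG_Actin_WH2_2	[ILMVF].{4,7}L[KR][KR][TV]	LIG	0	
LIG_LIR_Gen_1	[EDST].{0,2}[WFY][^RKPGWFY][^PG][ILVFM]	LIG	0	
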