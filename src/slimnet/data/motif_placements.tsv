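member	interactor	sites	site_kind
T1	FBXW11	DEG_SCF_TRCP1_1;DEG_Nend_Nbox_1	slim
T1	YWHAB	LIG_14-3-3_2	slim
T1	PPP1CA	DOC_PP1_RVXF_1	slim
T1	XPO1	TRG_NES_CRM1_1	slim
T2	YWHAB	LIG_14-3-3_2;LIG_14-3-3_3	slim
T2	PPP1CA	DOC_PP1_RVXF_1	slim
T2	NR2C2	LIG_NRBOX	slim
T2	XPO1	TRG_NES_CRM1_1	slim
T2	LATS2	MOD_LATS_1	slim
T2	Homer	LIG_EVH1_1	slim
T2	SCRIB	LIG_PDZ_Class_1	slim
T2	FBXW11	DEG_SCF_TRCP1_1;DEG_Nend_Nbox_1	slim
T2	Fodrin	ANK;TPR	domain
T2	MINK	TPR	domain
T2	TNIK	TPR	domain
T1	CDK	MOD_CDK_1	slim
both	G-Actin	LIG_Actin_WH2_2	slim
both	Cyclins	DOC_CYCLIN_1	slim
both	MAPK	DOC_MAPK_gen_1	slim
both	WW domain-containing protein	DOC_WW_Pin1_4	slim
both	Atg8 protein family	LIG_LIR_Gen_1	slim
both	CK1	MOD_CK1_1	slim
both	GSK3	MOD_GSK3_1	slim
both	NEK2	MOD_NEK2_1	slim
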