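member	site	site_kind
both	LIG_PDZ_Class_1	slim
both	DOC_PP1_RVXF_1	slim
both	DEG_Nend_Nbox_1	slim
both	DEG_SCF_TRCP1_1	slim
both	LIG_14-3-3_2	slim
both	MOD_NEK2_1	slim
both	TRG_NES_CRM1_1	slim
both	MOD_GSK3_1	slim
both	MOD_CK1_1	slim
both	DOC_MAPK_gen_1	slim
both	DOC_WW_Pin1_4	slim
both	LIG_Actin_WH2_2	slim
both	DOC_CYCLIN_1	slim
both	LIG_LIR_Gen_1	slim
T1	MOD_CDK_1	slim
T2	LIG_14-3-3_3	slim
T2	LIG_NRBOX	slim
T2	LIG_EVH1_1	slim
T2	MOD_LATS_1	slim
both	ANK	domain
both	TPR	domain
both	NTPase	domain
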