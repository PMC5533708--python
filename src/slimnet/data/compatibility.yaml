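# Binder domain class -> motif classes it recognises.
# Keys are matched against interaction-table domain-architecture entries
# after stripping leading copy counts, case-insensitively.
PDZ: [LIG_PDZ_Class_1]
"14-3-3": [LIG_14-3-3_2, LIG_14-3-3_3]
Ser/Thr phosphatase: [DOC_PP1_RVXF_1]
F-box: [DEG_SCF_TRCP1_1, DEG_Nend_Nbox_1]
Importin_N-term: [TRG_NES_CRM1_1]
NHR ligand binding: [LIG_NRBOX]
AGC-kinase C-terminal: [MOD_LATS_1]
WH1/EVH1: [LIG_EVH1_1]
WW domain: [DOC_WW_Pin1_4]
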