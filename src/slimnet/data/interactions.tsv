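name	member	method	binding_region	domain_architecture	pathway
alpha-internexin	T1	Co-IP	unknown	Intermediate filament head;DNA-binding	Cytoskeleton organization
CAMKIIa	T1	Co-IP	unknown	Kinase	Glutamate Receptor signaling
CASK	T1	Pull-down assay	unknown	Casein Kappa	Glutamate Receptor signaling
CBY1	T2	SF-TAP/MS	unknown	Chibby_fam	Wnt/Wingless signaling, Cilium assembly
CDC5L	T2	HTS AC-MS	unknown	myb-HTH DNA binding type 1 and 2;Myb/Cef1 domain	Spliceosome assembly
CENPQ	T2	HTS AC-MS	unknown	CENP-Q domain;Coiled coil	Nucleosome assembly at the centromere
CEP120	T2	HTS AC-MS	unknown	2 C2;Coiled coil	Centrosome organization, Cilium assembly
CEP128	T1	HTS AC-MS	unknown	Coiled coil	Centrosome organization, Cilium assembly
CNTRL	T1	HTS AC-MS	unknown	4 LRR;4 Coiled coil	Centrosome organization, Cilium assembly
FBXW11	T1	Co-IP	unknown	F-box;7 WD repeats	Ubiquitin-mediated degradation
FMRP	T2	CLIP	unknown	Agenet-like;KH;FXMRP1_C_core;FXMR_C2	Regulation of translation
Fodrin	T1	Pull-down assay	ANK;TPR	23 Spectrin repeats;SH3;3 EF-hand	Cytoskeleton organization
GKAP	T1	Co-IP	unknown	3 Coiled coil	Glutamate Receptor signaling
GluR1	T1	Co-IP	unknown	TM	Glutamate Receptor signaling
GRIP	T1	Pull-down assay	unknown	7 PDZ	Glutamate Receptor signaling
Homer	T1	Pull-down assay	unknown	WH1/EVH1;Coiled coil	Glutamate Receptor signaling
INPP5E	T2	SF-TAP/MS	unknown	13 repeats of P-X-X-P;Phosphatase	Cilium trafficking
LATS2	T2	HTS PL-MS	unknown	UB associated Kinase;AGC-kinase C-terminal	Hippo pathway
MAPRE1	T2	SF-TAP/MS	unknown	CH;EB1_C	Microtubule cytoskeleton regulation, Cilium assembly
MOV10	T1	HTS AC-RNA	unknown	P-loop ATPase domain	RNA-mediated gene silencing
MINK	T1	Immunoblotting	TPR	Kinase;CNH	Rap2-mediated signaling
NINL	T1	HTS AC-MS	unknown	4 EF-hand;4 Coiled coil;KEN-box;D-box	Centrosome organization, Cilium assembly
NR2B	T1	Co-IP	unknown	Transmembrane receptor	Glutamate Receptor signaling
NR2C2	T2	HTS AC-MS	unknown	ZF-C4;NHR ligand binding	Nuclear receptor signaling pathways
NXF1	T1	HTS AC-RNA	unknown	RRM;4 LLR repeats;NTF2;TAP-C	mRNA export from nucleus
PAK7	T2	HTS AC-MS	unknown	CRIB;kinase	Planar Cell Polarity pathway
PCM1	T1	HTS AC-MS	unknown	Coiled coil;GTPase;molybdopterin domain	Centrosome organization, Cilium assembly
PPP1CA	T2	HTS AC-MS	unknown	Ser/Thr phosphatase	Glutamate Receptor signaling, Hippo, Wnt signaling
PPP1CC	T2	HTS AC-MS	unknown	Ser/Thr phosphatase	GluR, Hippo signaling
PRICKLE1	both	LC-MS/MS	unknown	PET;3 LIMs	Planar Cell Polarity pathway
PRICKLE2	both	LC-MS/MS	unknown	PET;3 LIMs	Planar Cell Polarity pathway
PSD-95	both	Y2H, Pull-down assay	LIG_PDZ_Class_1	3 PDZ;SH3;GK	Glutamate Receptor signaling
SAP97	both	Y2H, Pull-down assay	LIG_PDZ_Class_1	L27;3 PDZ;SH3;GK	Glutamate Receptor signaling
SCRIB	T1	SPR	LIG_PDZ_Class_1	16 LRR repeats;4 PDZ	Planar Cell Polarity pathway
SHANK1	T1	Pull-down assay	unknown	6 ANK;SH3;PDZ;SAM	Glutamate Receptor signaling
SPIRE2	T2	HTS AC-MS	unknown	KIND;3 WH2;ZF	Vescicle transport
TNIK	T1	Immunoblotting	TPR	Kinase;CNH	Rap2-mediated and Wnt signaling
XPO1	T2	Pull down	unknown	Importin_N-term;10 ARM/HEAT repeat like	Nuclear export
YWHAB	T2	HTS AC-MS	unknown	14-3-3	Glutamate Receptor signaling, Hippo signaling
ZYX	T2	HTS AC-MS	unknown	3 LIM;Zn binding	Hippo pathway
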