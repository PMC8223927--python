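family	accession	func_class	activity
Amidase_2	PF01510	EAD	NAM-amidase
Amidase_3	PF01520	EAD	NAM-amidase
Amidase_5	PF05382	EAD	NAM-amidase
CHAP	PF05257	EAD	amidase/peptidase
Glyco_hydro_25	PF01183	EAD	muramidase
Glyco_hydro_19	PF00182	EAD	glucosaminidase
Glyco_hydro_108	PF05838	EAD	muramidase
Phage_lysozyme	PF00959	EAD	muramidase
Muramidase	PF11860	EAD	muramidase
Glucosaminidase	PF01832	EAD	glucosaminidase
Peptidase_M15_4	PF13539	EAD	peptidase
Peptidase_M23	PF01551	EAD	peptidase
Peptidase_C39_2	PF13529	EAD	peptidase
Peptidase_M15_3	PF08291	EAD	peptidase
Transglycosylase	PF06737	EAD	transglycosylase
SLT	PF01464	EAD	transglycosylase
Hydrolase_2	PF07486	EAD	unknown
VanY	PF02557	EAD	peptidase
NLPC_P60	PF00877	EAD	peptidase
Cutinase	PF01083	EAD	esterase
FSH1	PF03959	EAD	esterase
PE-PPE	PF08237	EAD	esterase
CW_binding_1	PF01473	CWBD
CW_7	PF08230	CWBD
LysM	PF01476	CWBD
SH3_5	PF08460	CWBD
SH3_3	PF08239	CWBD
PG_binding_1	PF01471	CWBD
PG_binding_3	PF09374	CWBD
LGFP	PF08310	CWBD
ZoocinA_TRD	PF16775	CWBD
PSA_CBD	PF18341	CWBD
Amidase02_C	PF12123	CWBD
Gp5_C	PF06715	STRUCTURAL
Gp5_OB	PF06714	STRUCTURAL
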