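pfam	example
AMO	PMMO subunit A
AmoC	PMMO subunit C
Bac_luciferase	LadA
FA_desaturase	AlkB
MeMO_Hyd_G	SMMO subunit G
Monooxygenase_B	PMMO subunit B
p450	p450
Phenol_Hydrox	PMO small subunit
Pyr_redox_3	AlmA
MmoB_DmpM	regulatory component
ADH_zinc	alcohol dehydrogenase
LXG	misclassified
Nol1_Nop2_Fmu	misclassified
DUF900	misclassified
NAD_binding_1	reductase component
FAD_binding_6	reductase component
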