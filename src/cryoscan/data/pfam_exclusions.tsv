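pfam	reason
MmoB_DmpM	regulatory
ADH_zinc	electron carrier binding
LXG	erroneous classification
Nol1_Nop2_Fmu	erroneous classification
DUF900	erroneous classification
NAD_binding_1	electron carrier binding
FAD_binding_6	electron carrier binding
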