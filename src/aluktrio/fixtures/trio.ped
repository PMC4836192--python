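# family_id individual_id father_id mother_id sex phenotype preservation
FAM1	DO1911	0	0	1	0	ancient
FAM1	DO3756	0	0	2	0	ancient
FAM1	DO3750	DO1911	DO3756	2	0	ancient
CTRL	Cau_1	0	0	1	0	modern
CTRL	Cau_2	0	0	1	0	modern
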