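gene_id	old_name	ntf_domain_variability	soluble_ntf	anchored_ntf	ctf	tm7_variability	cterm_variability
ADGRL1	Lphn1	1	1	1	1	0	1
ADGRL2	Lphn2	1	0	0	1	0	1
ADGRL3	Lphn3	1	1	0	0	0	1
ADGRL4	Eltd1	1	0	0	0	0	0
ADGRE1	Emr1	1	0	0	1	0	1
ADGRE4	Emr4	0	1	0	1	0	1
ADGRE5	Cd97	1	1	1	0	0	0
ADGRA2	Gpr124	0	1	1	1	1	0
ADGRA3	Gpr125	0	0	0	1	0	0
ADGRC1	Celsr1	1	1	0	1	0	1
ADGRC2	Celsr2	1	0	0	1	0	1
ADGRD1	Gpr133	1	1	0	1	0	0
ADGRF5	Gpr116	1	1	0	0	0	1
ADGRB3	Bai3	1	0	0	1	1	0
ADGRG1	Gpr56	0	0	0	1	0	0
ADGRG2	Gpr64	1	1	0	0	0	1
ADGRG3	Gpr97	0	0	0	1	0	1
ADGRG6	Gpr126	1	1	1	0	0	0
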