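gene_id	old_name	n_annotated_ncbi_variants	n_start	n_start_annotated	n_end	n_end_annotated	n_internal	n_internal_annotated	n_variants	n_abundant	n_exons_total	n_exons_abundant	mean_exons_abundant	min_exons_abundant	max_exons_abundant
ADGRL1	Lphn1	14	22	6	19	1	91	24	118	56	132	83	14.5	2	25
ADGRL2	Lphn2	51	29	4	24	6	51	35	108	37	104	57	15.5	2	22
ADGRL3	Lphn3	36	28	3	29	7	42	36	69	9	99	37	17.2	2	26
ADGRL4	Eltd1	1	16	1	13	1	22	14	59	3	51	16	15.4	15	16
ADGRE1	Emr1	4	19	1	9	2	39	22	52	9	67	31	17.2	3	22
ADGRE4	Emr4	1	16	1	11	1	31	17	41	4	58	24	14.3	8	17
ADGRE5	Cd97	7	16	1	13	1	48	20	117	19	77	31	17.3	2	21
ADGRA2	Gpr124	5	16	2	16	3	41	19	74	29	73	49	12.8	3	20
ADGRA3	Gpr125	1	17	1	16	1	31	18	66	6	64	22	13.2	2	19
ADGRC1	Celsr1	5	16	2	8	1	46	34	26	9	70	49	22.9	4	35
ADGRC2	Celsr2	5	23	2	15	1	56	33	49	22	94	65	20.8	3	34
ADGRD1	Gpr133	3	9	2	10	1	32	26	33	7	51	31	21.0	10	26
ADGRF5	Gpr116	8	23	2	13	1	43	29	105	19	79	32	20.8	15	22
ADGRB3	Bai3	4	18	3	6	1	39	33	41	11	63	39	18.6	3	31
ADGRG1	Gpr56	19	19	10	9	2	23	15	67	9	51	21	13.7	5	14
ADGRG2	Gpr64	22	17	3	10	1	35	30	56	32	62	45	21.8	3	29
ADGRG3	Gpr97	5	11	3	12	1	22	14	52	24	45	36	7.9	3	12
ADGRG6	Gpr126	7	12	3	6	2	32	24	29	22	50	42	16.4	2	26
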