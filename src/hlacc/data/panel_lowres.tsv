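locus	allele	frequency	frequency_unit	n	n_unit
A	A*01	0.12	fraction	11516	alleles
A	A*02	0.26	fraction	11516	alleles
A	A*03	0.09	fraction	11516	alleles
A	A*11	0.08	fraction	11516	alleles
A	A*23	0.03	fraction	11516	alleles
A	A*24	0.12	fraction	11516	alleles
A	A*25	0.03	fraction	11516	alleles
A	A*26	0.05	fraction	11516	alleles
A	A*29	0.02	fraction	11516	alleles
A	A*30	0.02	fraction	11516	alleles
A	A*31	0.02	fraction	11516	alleles
A	A*32	0.04	fraction	11516	alleles
A	A*33	0.03	fraction	11516	alleles
A	A*36	0.04	fraction	11516	alleles
A	A*68	0.03	fraction	11516	alleles
B	B*07	0.05	fraction	12020	alleles
B	B*08	0.06	fraction	12020	alleles
B	B*13	0.03	fraction	12020	alleles
B	B*14	0.02	fraction	12020	alleles
B	B*15	0.03	fraction	12020	alleles
B	B*18	0.1	fraction	12020	alleles
B	B*27	0.04	fraction	12020	alleles
B	B*35	0.14	fraction	12020	alleles
B	B*38	0.03	fraction	12020	alleles
B	B*39	0.03	fraction	12020	alleles
B	B*40	0.05	fraction	12020	alleles
B	B*41	0.02	fraction	12020	alleles
B	B*44	0.08	fraction	12020	alleles
B	B*47	0.0	fraction	12020	alleles
B	B*49	0.02	fraction	12020	alleles
B	B*50	0.02	fraction	12020	alleles
B	B*51	0.09	fraction	12020	alleles
B	B*52	0.04	fraction	12020	alleles
B	B*53	0.02	fraction	12020	alleles
B	B*55	0.02	fraction	12020	alleles
B	B*56	0.01	fraction	12020	alleles
B	B*57	0.01	fraction	12020	alleles
B	B*58	0.02	fraction	12020	alleles
B	B*73	0.0	fraction	12020	alleles
B	B*78	0.03	fraction	12020	alleles
C	C*01	0.05	fraction	3224	alleles
C	C*02	0.07	fraction	3224	alleles
C	C*03	0.07	fraction	3224	alleles
C	C*04	0.15	fraction	3224	alleles
C	C*05	0.03	fraction	3224	alleles
C	C*06	0.09	fraction	3224	alleles
C	C*07	0.26	fraction	3224	alleles
C	C*08	0.03	fraction	3224	alleles
C	C*12	0.13	fraction	3224	alleles
C	C*14	0.03	fraction	3224	alleles
C	C*15	0.05	fraction	3224	alleles
C	C*16	0.03	fraction	3224	alleles
C	C*17	0.01	fraction	3224	alleles
DRB1	DRB1*01	0.08	fraction	13872	alleles
DRB1	DRB1*03	0.11	fraction	13872	alleles
DRB1	DRB1*04	0.09	fraction	13872	alleles
DRB1	DRB1*07	0.07	fraction	13872	alleles
DRB1	DRB1*08	0.02	fraction	13872	alleles
DRB1	DRB1*10	0.01	fraction	13872	alleles
DRB1	DRB1*11	0.19	fraction	13872	alleles
DRB1	DRB1*12	0.02	fraction	13872	alleles
DRB1	DRB1*13	0.15	fraction	13872	alleles
DRB1	DRB1*14	0.07	fraction	13872	alleles
DRB1	DRB1*15	0.09	fraction	13872	alleles
DRB1	DRB1*16	0.1	fraction	13872	alleles
DQB1	DQB1*02	0.21	fraction	6656	alleles
DQB1	DQB1*03	0.29	fraction	6656	alleles
DQB1	DQB1*04	0.02	fraction	6656	alleles
DQB1	DQB1*05	0.3	fraction	6656	alleles
DQB1	DQB1*06	0.18	fraction	6656	alleles
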