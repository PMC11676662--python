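locus	allele	frequency	frequency_unit	n	n_unit
A	A*02:07	0.0004	fraction	2468	alleles
A	A*02:08	0.0004	fraction	2468	alleles
A	A*02:27	0.0004	fraction	2468	alleles
A	A*02:36	0.0	fraction	2468	alleles
A	A*03:97	0.0004	fraction	2468	alleles
A	A*24:18	0.0004	fraction	2468	alleles
A	A*68:18N	0.0004	fraction	2468	alleles
A	A*74:01	0.0004	fraction	2468	alleles
A	A*80:01	0.0004	fraction	2468	alleles
B	B*15:09	0.0004	fraction	2468	alleles
B	B*15:39	0.0004	fraction	2468	alleles
B	B*15:73	0.0004	fraction	2468	alleles
B	B*35:14	0.0004	fraction	2468	alleles
B	B*39:10	0.0004	fraction	2468	alleles
B	B*39:31	0.0004	fraction	2468	alleles
B	B*44:04	0.0004	fraction	2468	alleles
B	B*44:27	0.0	fraction	2468	alleles
B	B*47:27	0.0	fraction	2468	alleles
B	B*51:02	0.0005	fraction	2468	alleles
B	B*53:01	0.0004	fraction	2468	alleles
B	B*57:02	0.0008	fraction	2468	alleles
C	C*08:01	0.0004	fraction	2468	alleles
C	C*12:12	0.0004	fraction	2468	alleles
C	C*15:06	0.0004	fraction	2468	alleles
DRB1	DRB1*01:11	0.0004	fraction	2468	alleles
DRB1	DRB1*11:11	0.0004	fraction	2468	alleles
DRB1	DRB1*11:33	0.0004	fraction	2468	alleles
DRB1	DRB1*11:39	0.0004	fraction	2468	alleles
DRB1	DRB1*11:43	0.0004	fraction	2468	alleles
DRB1	DRB1*13:22	0.0004	fraction	2468	alleles
DRB1	DRB1*14:06	0.0004	fraction	2468	alleles
DRB1	DRB1*14:54	0.0	fraction	2468	alleles
DRB1	DRB1*16:01	0.0644	fraction	2468	alleles
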