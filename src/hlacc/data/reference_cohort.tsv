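subject_id	A_1	A_2	B_1	B_2	C_1	C_2	DRB1_1	DRB1_2	DQB1_1	DQB1_2	sex	age_at_onset	onset_class	mgfa_max	serotype	thymic_status	autoimmune	titin_ryr
MG01	A*02:01	A*02:36	B*08:01	B*40:01	C*01:01	C*07:01	DRB1*01:01	DRB1*03:01	DQB1*02:01	DQB1*05:01	F	25	EOMG	IIA	RAchPos	thymoma	1	none
MG02	A*01:01	A*02:01	B*18:01	B*40:01	C*02:01	C*07:01	DRB1*01:01	DRB1*07:01	DQB1*02:01	DQB1*05:01	F	30	EOMG	IIA	RAchPos	thymoma	1	none
MG03	A*01:01	A*02:01	B*35:01	B*40:01	C*02:01	C*07:01	DRB1*01:01	DRB1*11:01	DQB1*02:01	DQB1*05:01	F	35	EOMG	IIB	RAchPos	thymoma	1	none
MG04	A*01:01	A*03:01	B*35:01	B*40:01	C*02:01	C*07:01	DRB1*01:01	DRB1*11:01	DQB1*02:01	DQB1*05:01	F	40	EOMG	IIB	RAchPos	follicular_hyperplasia	1	none
MG05	A*01:01	A*03:01	B*40:01	B*47:27	C*02:01	C*07:01	DRB1*01:01	DRB1*14:01	DQB1*02:01	DQB1*05:01	F	45	EOMG	V	RAchPos	normal_ct	0	none
MG06	A*01:01	A*03:01	B*40:01	B*51:01	C*02:01	C*07:01	DRB1*01:01	DRB1*15:01	DQB1*02:01	DQB1*05:01	F	47	EOMG	V	RAchPos	normal_ct	0	none
MG07	A*01:01	A*24:01	B*07:01	B*35:01	C*02:01	C*07:01	DRB1*01:01	DRB1*16:01	DQB1*02:01	DQB1*05:01	F	15	MGj	IIA	RAchPos	follicular_hyperplasia	1	none
MG08	A*01:01	A*24:01	B*07:01	B*35:01	C*03:01	C*07:01	DRB1*03:01	DRB1*14:54	DQB1*02:01	DQB1*05:01	F	16	MGj	IIA	RAchPos	follicular_hyperplasia	1	none
MG09	A*01:01	A*32:01	B*07:01	B*44:27	C*03:01	C*07:01	DRB1*03:01	DRB1*14:54	DQB1*03:01	DQB1*05:01	F	28	EOMG	I	RAchPos	thymoma	1	none
MG10	A*01:01	A*32:01	B*08:01	B*15:01	C*03:01	C*07:01	DRB1*03:01	DRB1*15:01	DQB1*03:01	DQB1*05:01	F	32	EOMG	I	RAchPos	thymoma	1	none
MG11	A*02:01	A*02:01	B*08:01	B*18:01	C*03:01	C*07:01	DRB1*03:01	DRB1*16:01	DQB1*03:01	DQB1*05:01	F	36	EOMG	I	RAchPos	follicular_hyperplasia	1	none
MG12	A*02:01	A*02:01	B*08:01	B*35:01	C*03:01	C*07:01	DRB1*03:01	DRB1*16:01	DQB1*03:01	DQB1*05:01	F	38	EOMG	I	RAchPos	normal_ct	1	none
MG13	A*02:01	A*02:01	B*08:01	B*38:01	C*04:01	C*07:01	DRB1*03:01	DRB1*16:01	DQB1*03:01	DQB1*05:01	F	42	EOMG	IIB	RAchPos	normal_ct	0	titin_and_ryr
MG14	A*02:01	A*02:01	B*08:01	B*39:01	C*04:01	C*07:01	DRB1*04:01	DRB1*15:01	DQB1*03:01	DQB1*05:01	F	55	LOMG	IIB	RAchPos	normal_ct	0	titin_and_ryr
MG15	A*02:01	A*11:01	B*08:01	B*44:01	C*04:01	C*07:01	DRB1*04:01	DRB1*15:01	DQB1*03:01	DQB1*05:01	F	60	LOMG	IIA	RAchPos	normal_ct	0	titin_only
MG16	A*02:01	A*24:01	B*08:01	B*44:01	C*04:01	C*07:01	DRB1*04:01	DRB1*15:01	DQB1*03:01	DQB1*05:01	F	44	EOMG	I	RAchPos	normal_ct	0	none
MG17	A*02:01	A*24:01	B*08:01	B*73:01	C*04:01	C*12:01	DRB1*04:01	DRB1*16:01	DQB1*03:01	DQB1*05:01	F	52	LOMG	IIA	RAchPos	thymoma	0	none
MG18	A*02:01	A*25:01	B*13:01	B*35:01	C*04:01	C*12:01	DRB1*04:01	DRB1*16:01	DQB1*03:01	DQB1*05:01	F	58	LOMG	IIA	RAchPos	follicular_hyperplasia	0	none
MG19	A*02:01	A*26:01	B*13:01	B*51:01	C*04:01	C*12:01	DRB1*04:01	DRB1*16:01	DQB1*03:01	DQB1*05:01	F	62	LOMG	IIA	RAchPos	normal_ct	0	none
MG20	A*02:01	A*26:01	B*15:01	B*18:01	C*05:01	C*12:01	DRB1*07:01	DRB1*11:01	DQB1*03:01	DQB1*05:01	F	65	LOMG	IIA	RAchPos	normal_ct	0	none
MG21	A*02:01	A*29:01	B*18:01	B*39:01	C*06:01	C*12:01	DRB1*07:01	DRB1*15:01	DQB1*03:01	DQB1*06:01	F	68	LOMG	IIA	RAchPos	normal_ct	0	none
MG22	A*02:01	A*32:01	B*18:01	B*44:01	C*06:01	C*12:01	DRB1*10:01	DRB1*16:01	DQB1*03:01	DQB1*06:01	F	78	LOMG	IIA	RAchPos	normal_ct	0	none
MG23	A*03:01	A*32:01	B*18:01	B*51:01	C*06:01	C*12:01	DRB1*11:01	DRB1*11:01	DQB1*03:01	DQB1*06:01	M	24	EOMG	IIA	RAchPos	normal_ct	0	none
MG24	A*03:01	A*33:01	B*27:01	B*35:01	C*06:01	C*14:01	DRB1*11:01	DRB1*12:01	DQB1*03:01	DQB1*06:01	M	54	LOMG	IIB	RAchPos	thymoma	0	none
MG25	A*11:01	A*24:01	B*27:01	B*51:01	C*06:01	C*15:01	DRB1*11:01	DRB1*15:01	DQB1*03:01	DQB1*06:01	M	57	LOMG	IIB	RAchPos	follicular_hyperplasia	0	none
MG26	A*23:01	A*68:01	B*27:01	B*57:02	C*06:01	C*15:01	DRB1*11:01	DRB1*15:01	DQB1*05:01	DQB1*06:01	M	33	EOMG	IIB	RAchPos	follicular_hyperplasia	0	none
MG27	A*24:01	A*24:01	B*35:01	B*44:01	C*06:01	C*15:01	DRB1*11:01	DRB1*16:01	DQB1*05:01	DQB1*06:01	M	37	EOMG	IIB	RAchPos	normal_ct	0	none
MG28	A*24:01	A*25:01	B*35:01	B*52:01	C*07:01	C*15:01	DRB1*11:01	DRB1*16:01	DQB1*05:01	DQB1*06:01	M	41	EOMG	IIIB	RAchPos	normal_ct	0	none
MG29	A*26:01	A*26:01	B*38:01	B*57:02	C*07:01	C*16:01	DRB1*14:01	DRB1*16:01	DQB1*05:01	DQB1*06:01	M	46	EOMG	IIIB	RAchPos	normal_ct	0	none
MG30	A*31:01	A*32:01	B*44:01	B*51:01	C*07:01	C*16:01	DRB1*15:01	DRB1*16:02			M	48	EOMG	V	RAchPos	normal_ct	0	none
MG31	A*01:01	A*01:01	B*08:01	B*51:01	C*07:01	C*12:01	DRB1*07:01	DRB1*14:54	DQB1*03:01	DQB1*05:01	F	39	EOMG	V	MuSKPos	normal_ct	0	none
MG32	A*02:01	A*30:01	B*40:01	B*47:27	C*01:01	C*07:01	DRB1*04:01	DRB1*13:02	DQB1*02:01	DQB1*05:01	F	1	MGj	IIB	dSNMG	normal_ct	1	none
MG33	A*25:01	A*33:01	B*18:01	B*40:01	C*01:01	C*07:01	DRB1*10:01	DRB1*14:54	DQB1*02:01	DQB1*05:01	F	66	LOMG	IIA	dSNMG	normal_ct	0	none
MG34	A*02:01	A*03:01	B*08:01	B*55:01	C*01:01	C*07:01	DRB1*03:01	DRB1*11:01	DQB1*02:01	DQB1*05:01	F	50	LOMG	V	dSNMG	thymoma	0	none
MG35	A*01:01	A*02:01	B*51:01	B*58:01	C*02:01	C*07:01	DRB1*01:01	DRB1*07:01	DQB1*03:01	DQB1*05:01	F	53	LOMG	V	dSNMG	thymoma	0	none
MG36	A*01:01	A*02:01	B*08:01	B*18:01	C*02:01	C*07:01	DRB1*07:01	DRB1*11:01	DQB1*03:01	DQB1*05:01	F	63	LOMG	V	dSNMG	follicular_hyperplasia	0	none
MG37	A*02:01	A*24:01	B*18:01	B*38:01	C*03:01	C*06:01	DRB1*01:01	DRB1*14:54	DQB1*03:01	DQB1*05:01	F	22	EOMG	V	dSNMG	follicular_hyperplasia	0	none
MG38	A*02:01	A*24:01	B*13:01	B*27:01	C*04:01	C*06:01	DRB1*11:01	DRB1*16:01	DQB1*03:01	DQB1*05:01	F	26	EOMG	IIB	dSNMG	normal_ct	0	none
MG39	A*02:01	A*24:01	B*35:01	B*44:27	C*12:01	C*14:01	DRB1*11:01	DRB1*16:01	DQB1*03:01	DQB1*06:01	F	29	EOMG	IIA	dSNMG	normal_ct	0	none
MG40	A*02:01	A*24:01	B*35:01	B*51:01	C*12:01	C*15:01	DRB1*14:01	DRB1*15:01	DQB1*05:01	DQB1*06:01	F	31	EOMG	IIB	dSNMG	normal_ct	0	none
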