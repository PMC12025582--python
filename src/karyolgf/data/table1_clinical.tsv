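# Clinical features of the 37 OSU tetraploid/near-tetraploid MDS/AML cases.
# Columns: case_id, age at T/NT identification (years), gender, interval between
# MDS/AML diagnosis and T/NT identification (months; NA = not available),
# diagnosis, prior treatment (Yes/No/NA), treatment received, T/NT clone size
# (% of cells), T/NT persistence after treatment (Yes/No/NA), overall survival
# (months from T/NT identification), outcome code.
# Outcome codes: DOD died of disease; ANED alive no evidence of disease;
# AWD alive with disease; LFU lost to follow-up; "LFU—hospice" discharged to hospice.
case_id	age_years	gender	interval_months	diagnosis	prior_treatment	treatment	tnt_clone_size_pct	tnt_persistence	os_months	outcome	cohort
1	63	M	0	MDS-EB1	No	Chemo	21	No	2.5	DOD	OSU
2	65	M	0	AML-MRC	No	Chemo	95	No	3	DOD	OSU
3	89	M	0	Histiocytic sarcoma	No	No	20	NA	1	DOD	OSU
4	89	F	0	AML-MRC	No	Chemo	75	NA	1.5	DOD	OSU
5	84	M	0	AML-MRC	No	Chemo	85	Yes	15	DOD	OSU
6	78	F	0	AML-MRC	No	Chemo	74	Yes	2	DOD	OSU
7	67	M	0	MDS-EB1/evolving AML	No	Chemo	25	Yes	11	DOD	OSU
8	85	M	0	AML-MRC	No	Chemo	35	NA	27	DOD	OSU
9	69	M	48	AML, NOS	Yes	Chemo	75	Yes	24	DOD	OSU
10	79	M	2.5	AML, NOS	Yes	Chemo	10	No	3	LFU—hospice	OSU
11	87	M	0	AML-MRC	No	No	90	NA	0.25	LFU—hospice	OSU
12	58	M	0	AML-MRC	No	Chemo	85	NA	3.5	DOD	OSU
13	70	F	0	Myeloid sarcoma/AUL	No	Chemo	90	No	4.5	LFU—hospice	OSU
14	57	M	0	AML-MRC	No	Chemo	100	No	15	DOD	OSU
15	72	M	84	AML, NOS	Yes	Chemo	25	Yes	2	DOD	OSU
16	61	M	0	AML-MRC	NA	Chemo	30	No	3.5	DOD	OSU
17	65	M	NA	AML-MRC	NA	Chemo	90	No	4	DOD	OSU
18	52	M	0	MDS-EB2	No	Chemo	95	NA	4	DOD	OSU
19	58	M	0	AML-MRC	No	Chemo	15	Yes	11	DOD	OSU
20	66	M	0	AML-MRC	No	Chemo	25	Yes	1	DOD	OSU
21	75	F	8	AML t(8;21)	Yes	Chemo	100	Yes	6	LFU	OSU
22	24	M	0	AML-MRC	No	Chemo, SCT	85	No	146	ANED	OSU
23	71	M	0	AML, NOS	No	Chemo	55	Yes	23	DOD	OSU
24	69	F	0	AML-MRC	No	Chemo, SCT	100	No	6.5	DOD	OSU
25	29	F	0	AUL	No	Chemo, SCT	13	No	105	ANED	OSU
26	62	F	21	AML-MRC	Yes	Chemo	85	Yes	1.5	DOD	OSU
27	77	M	0	MDS-MLD	No	No	35	NA	4	DOD	OSU
28	61	M	0	AML-MRC	No	Chemo, SCT	43	No	9	DOD	OSU
29	69	F	0	AML-MRC	No	Chemo	10	Yes	16	LFU	OSU
30	69	F	NA	AML-MRC	Yes	Chemo	20	Yes	1.5	LFU	OSU
31	78	M	4	AML-MRC	Yes	Chemo	70	Yes	6	DOD	OSU
32	69	M	0	MDS-EB2	No	Chemo	35	No	27	ANED	OSU
33	38	F	0	AUL	No	Chemo, SCT	22	No	19	ANED	OSU
34	46	M	0	AML, NOS	No	Chemo, SCT	22	No	21	ANED	OSU
35	82	F	0	AML-MRC	No	Chemo	60	Yes	3	DOD	OSU
36	61	F	20	AML inv(3)	Yes	Chemo, SCT	5	Yes	12	DOD	OSU
37	74	F	0	AML-MRC	No	Chemo	10	Yes	17	AWD	OSU
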