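residue_name	atom_name	type_id	role
ALA	N	0	protein
ALA	CA	1	protein
ALA	C	2	protein
ALA	O	3	protein
ALA	CB	4	protein
ARG	N	5	protein
ARG	CA	6	protein
ARG	C	7	protein
ARG	O	8	protein
ARG	CB	9	protein
ARG	CG	10	protein
ARG	CD	11	protein
ARG	NE	12	protein
ARG	CZ	13	protein
ARG	NH1	14	protein
ARG	NH2	15	protein
ASN	N	16	protein
ASN	CA	17	protein
ASN	C	18	protein
ASN	O	19	protein
ASN	CB	20	protein
ASN	CG	21	protein
ASN	OD1	22	protein
ASN	ND2	23	protein
ASP	N	24	protein
ASP	CA	25	protein
ASP	C	26	protein
ASP	O	27	protein
ASP	CB	28	protein
ASP	CG	29	protein
ASP	OD1	30	protein
ASP	OD2	31	protein
CYS	N	32	protein
CYS	CA	33	protein
CYS	C	34	protein
CYS	O	35	protein
CYS	CB	36	protein
CYS	SG	37	protein
GLN	N	38	protein
GLN	CA	39	protein
GLN	C	40	protein
GLN	O	41	protein
GLN	CB	42	protein
GLN	CG	43	protein
GLN	CD	44	protein
GLN	OE1	45	protein
GLN	NE2	46	protein
GLU	N	47	protein
GLU	CA	48	protein
GLU	C	49	protein
GLU	O	50	protein
GLU	CB	51	protein
GLU	CG	52	protein
GLU	CD	53	protein
GLU	OE1	54	protein
GLU	OE2	55	protein
GLY	N	56	protein
GLY	CA	57	protein
GLY	C	58	protein
GLY	O	59	protein
HIS	N	60	protein
HIS	CA	61	protein
HIS	C	62	protein
HIS	O	63	protein
HIS	CB	64	protein
HIS	CG	65	protein
HIS	ND1	66	protein
HIS	CD2	67	protein
HIS	CE1	68	protein
HIS	NE2	69	protein
ILE	N	70	protein
ILE	CA	71	protein
ILE	C	72	protein
ILE	O	73	protein
ILE	CB	74	protein
ILE	CG1	75	protein
ILE	CG2	76	protein
ILE	CD1	77	protein
LEU	N	78	protein
LEU	CA	79	protein
LEU	C	80	protein
LEU	O	81	protein
LEU	CB	82	protein
LEU	CG	83	protein
LEU	CD1	84	protein
LEU	CD2	85	protein
LYS	N	86	protein
LYS	CA	87	protein
LYS	C	88	protein
LYS	O	89	protein
LYS	CB	90	protein
LYS	CG	91	protein
LYS	CD	92	protein
LYS	CE	93	protein
LYS	NZ	94	protein
MET	N	95	protein
MET	CA	96	protein
MET	C	97	protein
MET	O	98	protein
MET	CB	99	protein
MET	CG	100	protein
MET	SD	101	protein
MET	CE	102	protein
PHE	N	103	protein
PHE	CA	104	protein
PHE	C	105	protein
PHE	O	106	protein
PHE	CB	107	protein
PHE	CG	108	protein
PHE	CD1	109	protein
PHE	CD2	110	protein
PHE	CE1	111	protein
PHE	CE2	112	protein
PHE	CZ	113	protein
PRO	N	114	protein
PRO	CA	115	protein
PRO	C	116	protein
PRO	O	117	protein
PRO	CB	118	protein
PRO	CG	119	protein
PRO	CD	120	protein
SER	N	121	protein
SER	CA	122	protein
SER	C	123	protein
SER	O	124	protein
SER	CB	125	protein
SER	OG	126	protein
THR	N	127	protein
THR	CA	128	protein
THR	C	129	protein
THR	O	130	protein
THR	CB	131	protein
THR	OG1	132	protein
THR	CG2	133	protein
TRP	N	134	protein
TRP	CA	135	protein
TRP	C	136	protein
TRP	O	137	protein
TRP	CB	138	protein
TRP	CG	139	protein
TRP	CD1	140	protein
TRP	CD2	141	protein
TRP	NE1	142	protein
TRP	CE2	143	protein
TRP	CE3	144	protein
TRP	CZ2	145	protein
TRP	CZ3	146	protein
TRP	CH2	147	protein
TYR	N	148	protein
TYR	CA	149	protein
TYR	C	150	protein
TYR	O	151	protein
TYR	CB	152	protein
TYR	CG	153	protein
TYR	CD1	154	protein
TYR	CD2	155	protein
TYR	CE1	156	protein
TYR	CE2	157	protein
TYR	CZ	158	protein
TYR	OH	159	protein
VAL	N	160	protein
VAL	CA	161	protein
VAL	C	162	protein
VAL	O	163	protein
VAL	CB	164	protein
VAL	CG1	165	protein
VAL	CG2	166	protein
DA	P	1000	dna
DA	OP1	1001	dna
DA	OP2	1002	dna
DA	O5'	1003	dna
DA	C5'	1004	dna
DA	C4'	1005	dna
DA	O4'	1006	dna
DA	C3'	1007	dna
DA	O3'	1008	dna
DA	C2'	1009	dna
DA	C1'	1010	dna
DA	N9	1011	dna
DA	C8	1012	dna
DA	N7	1013	dna
DA	C5	1014	dna
DA	C4	1015	dna
DA	N3	1016	dna
DA	C2	1017	dna
DA	N1	1018	dna
DA	C6	1019	dna
DA	N6	1020	dna
DC	P	1021	dna
DC	OP1	1022	dna
DC	OP2	1023	dna
DC	O5'	1024	dna
DC	C5'	1025	dna
DC	C4'	1026	dna
DC	O4'	1027	dna
DC	C3'	1028	dna
DC	O3'	1029	dna
DC	C2'	1030	dna
DC	C1'	1031	dna
DC	N1	1032	dna
DC	C2	1033	dna
DC	N3	1034	dna
DC	C4	1035	dna
DC	C5	1036	dna
DC	C6	1037	dna
DC	O2	1038	dna
DC	N4	1039	dna
DG	P	1040	dna
DG	OP1	1041	dna
DG	OP2	1042	dna
DG	O5'	1043	dna
DG	C5'	1044	dna
DG	C4'	1045	dna
DG	O4'	1046	dna
DG	C3'	1047	dna
DG	O3'	1048	dna
DG	C2'	1049	dna
DG	C1'	1050	dna
DG	N9	1051	dna
DG	C8	1052	dna
DG	N7	1053	dna
DG	C5	1054	dna
DG	C4	1055	dna
DG	N3	1056	dna
DG	C2	1057	dna
DG	N1	1058	dna
DG	C6	1059	dna
DG	O6	1060	dna
DG	N2	1061	dna
DT	P	1062	dna
DT	OP1	1063	dna
DT	OP2	1064	dna
DT	O5'	1065	dna
DT	C5'	1066	dna
DT	C4'	1067	dna
DT	O4'	1068	dna
DT	C3'	1069	dna
DT	O3'	1070	dna
DT	C2'	1071	dna
DT	C1'	1072	dna
DT	N1	1073	dna
DT	C2	1074	dna
DT	N3	1075	dna
DT	C4	1076	dna
DT	C5	1077	dna
DT	C6	1078	dna
DT	O2	1079	dna
DT	O4	1080	dna
DT	C7	1081	dna
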