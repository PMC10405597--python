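# united-atom scattering groups, v1
# residue	atom	element	electrons	radius_A
*	N	N	8	1.60
*	CA	C	7	1.90
*	C	C	6	1.72
*	O	O	8	1.52
*	OXT	O	8	1.52
GLY	CA	C	8	1.95
PRO	N	N	7	1.55
ALA	CB	C	9	2.00
ARG	CB	C	8	1.95
ARG	CD	C	8	1.95
ARG	CG	C	8	1.95
ARG	CZ	C	6	1.72
ARG	NE	N	8	1.60
ARG	NH1	N	9	1.65
ARG	NH2	N	9	1.65
ASN	CB	C	8	1.95
ASN	CG	C	6	1.72
ASN	ND2	N	9	1.65
ASN	OD1	O	8	1.52
ASP	CB	C	8	1.95
ASP	CG	C	6	1.72
ASP	OD1	O	8	1.52
ASP	OD2	O	8	1.52
CYS	CB	C	8	1.95
CYS	SG	S	17	1.85
GLN	CB	C	8	1.95
GLN	CD	C	6	1.72
GLN	CG	C	8	1.95
GLN	NE2	N	9	1.65
GLN	OE1	O	8	1.52
GLU	CB	C	8	1.95
GLU	CD	C	6	1.72
GLU	CG	C	8	1.95
GLU	OE1	O	8	1.52
GLU	OE2	O	8	1.52
HIS	CB	C	8	1.95
HIS	CD2	C	7	1.82
HIS	CE1	C	7	1.82
HIS	CG	C	6	1.72
HIS	ND1	N	8	1.60
HIS	NE2	N	7	1.55
ILE	CB	C	7	1.90
ILE	CD1	C	9	2.00
ILE	CG1	C	8	1.95
ILE	CG2	C	9	2.00
LEU	CB	C	8	1.95
LEU	CD1	C	9	2.00
LEU	CD2	C	9	2.00
LEU	CG	C	7	1.90
LYS	CB	C	8	1.95
LYS	CD	C	8	1.95
LYS	CE	C	8	1.95
LYS	CG	C	8	1.95
LYS	NZ	N	10	1.70
MET	CB	C	8	1.95
MET	CE	C	9	2.00
MET	CG	C	8	1.95
MET	SD	S	16	1.80
PHE	CB	C	8	1.95
PHE	CD1	C	7	1.82
PHE	CD2	C	7	1.82
PHE	CE1	C	7	1.82
PHE	CE2	C	7	1.82
PHE	CG	C	6	1.72
PHE	CZ	C	7	1.82
PRO	CB	C	8	1.95
PRO	CD	C	8	1.95
PRO	CG	C	8	1.95
SER	CB	C	8	1.95
SER	OG	O	9	1.54
THR	CB	C	7	1.90
THR	CG2	C	9	2.00
THR	OG1	O	9	1.54
TRP	CB	C	8	1.95
TRP	CD1	C	7	1.82
TRP	CD2	C	6	1.72
TRP	CE2	C	6	1.72
TRP	CE3	C	7	1.82
TRP	CG	C	6	1.72
TRP	CH2	C	7	1.82
TRP	CZ2	C	7	1.82
TRP	CZ3	C	7	1.82
TRP	NE1	N	8	1.60
TYR	CB	C	8	1.95
TYR	CD1	C	7	1.82
TYR	CD2	C	7	1.82
TYR	CE1	C	7	1.82
TYR	CE2	C	7	1.82
TYR	CG	C	6	1.72
TYR	CZ	C	6	1.72
TYR	OH	O	9	1.54
VAL	CB	C	7	1.90
VAL	CG1	C	9	2.00
VAL	CG2	C	9	2.00
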