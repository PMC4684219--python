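# Atom-group assignments for standard-residue heavy atoms.
# Reconstruction: carbons split C_c/C_on by covalent O/N bonding;
# nitrogen/oxygen split by hydrogen-bond donor/acceptor capability.
# res_name	atom_name	group	group_name
ALA	C	5	C_ON
ALA	CA	5	C_ON
ALA	CB	4	C_C
ALA	N	0	N_DON
ALA	O	1	O_ACC
ALA	OXT	1	O_ACC
ARG	C	5	C_ON
ARG	CA	5	C_ON
ARG	CB	4	C_C
ARG	CD	5	C_ON
ARG	CG	4	C_C
ARG	CZ	5	C_ON
ARG	N	0	N_DON
ARG	NE	0	N_DON
ARG	NH1	0	N_DON
ARG	NH2	0	N_DON
ARG	O	1	O_ACC
ARG	OXT	1	O_ACC
ASN	C	5	C_ON
ASN	CA	5	C_ON
ASN	CB	4	C_C
ASN	CG	5	C_ON
ASN	N	0	N_DON
ASN	ND2	0	N_DON
ASN	O	1	O_ACC
ASN	OD1	1	O_ACC
ASN	OXT	1	O_ACC
ASP	C	5	C_ON
ASP	CA	5	C_ON
ASP	CB	4	C_C
ASP	CG	5	C_ON
ASP	N	0	N_DON
ASP	O	1	O_ACC
ASP	OD1	1	O_ACC
ASP	OD2	1	O_ACC
ASP	OXT	1	O_ACC
CYS	C	5	C_ON
CYS	CA	5	C_ON
CYS	CB	4	C_C
CYS	N	0	N_DON
CYS	O	1	O_ACC
CYS	OXT	1	O_ACC
CYS	SG	6	S
GLN	C	5	C_ON
GLN	CA	5	C_ON
GLN	CB	4	C_C
GLN	CD	5	C_ON
GLN	CG	4	C_C
GLN	N	0	N_DON
GLN	NE2	0	N_DON
GLN	O	1	O_ACC
GLN	OE1	1	O_ACC
GLN	OXT	1	O_ACC
GLU	C	5	C_ON
GLU	CA	5	C_ON
GLU	CB	4	C_C
GLU	CD	5	C_ON
GLU	CG	4	C_C
GLU	N	0	N_DON
GLU	O	1	O_ACC
GLU	OE1	1	O_ACC
GLU	OE2	1	O_ACC
GLU	OXT	1	O_ACC
GLY	C	5	C_ON
GLY	CA	5	C_ON
GLY	N	0	N_DON
GLY	O	1	O_ACC
GLY	OXT	1	O_ACC
HIS	C	5	C_ON
HIS	CA	5	C_ON
HIS	CB	4	C_C
HIS	CD2	5	C_ON
HIS	CE1	5	C_ON
HIS	CG	5	C_ON
HIS	N	0	N_DON
HIS	ND1	3	N_DA
HIS	NE2	3	N_DA
HIS	O	1	O_ACC
HIS	OXT	1	O_ACC
HOH	O	9	WAT
ILE	C	5	C_ON
ILE	CA	5	C_ON
ILE	CB	4	C_C
ILE	CD1	4	C_C
ILE	CG1	4	C_C
ILE	CG2	4	C_C
ILE	N	0	N_DON
ILE	O	1	O_ACC
ILE	OXT	1	O_ACC
LEU	C	5	C_ON
LEU	CA	5	C_ON
LEU	CB	4	C_C
LEU	CD1	4	C_C
LEU	CD2	4	C_C
LEU	CG	4	C_C
LEU	N	0	N_DON
LEU	O	1	O_ACC
LEU	OXT	1	O_ACC
LYS	C	5	C_ON
LYS	CA	5	C_ON
LYS	CB	4	C_C
LYS	CD	4	C_C
LYS	CE	5	C_ON
LYS	CG	4	C_C
LYS	N	0	N_DON
LYS	NZ	0	N_DON
LYS	O	1	O_ACC
LYS	OXT	1	O_ACC
MET	C	5	C_ON
MET	CA	5	C_ON
MET	CB	4	C_C
MET	CE	4	C_C
MET	CG	4	C_C
MET	N	0	N_DON
MET	O	1	O_ACC
MET	OXT	1	O_ACC
MET	SD	6	S
PHE	C	5	C_ON
PHE	CA	5	C_ON
PHE	CB	4	C_C
PHE	CD1	4	C_C
PHE	CD2	4	C_C
PHE	CE1	4	C_C
PHE	CE2	4	C_C
PHE	CG	4	C_C
PHE	CZ	4	C_C
PHE	N	0	N_DON
PHE	O	1	O_ACC
PHE	OXT	1	O_ACC
PRO	C	5	C_ON
PRO	CA	5	C_ON
PRO	CB	4	C_C
PRO	CD	5	C_ON
PRO	CG	4	C_C
PRO	N	8	N_PRO
PRO	O	1	O_ACC
PRO	OXT	1	O_ACC
SER	C	5	C_ON
SER	CA	5	C_ON
SER	CB	5	C_ON
SER	N	0	N_DON
SER	O	1	O_ACC
SER	OG	2	O_DA
SER	OXT	1	O_ACC
THR	C	5	C_ON
THR	CA	5	C_ON
THR	CB	5	C_ON
THR	CG2	4	C_C
THR	N	0	N_DON
THR	O	1	O_ACC
THR	OG1	2	O_DA
THR	OXT	1	O_ACC
TRP	C	5	C_ON
TRP	CA	5	C_ON
TRP	CB	4	C_C
TRP	CD1	5	C_ON
TRP	CD2	4	C_C
TRP	CE2	5	C_ON
TRP	CE3	4	C_C
TRP	CG	4	C_C
TRP	CH2	4	C_C
TRP	CZ2	4	C_C
TRP	CZ3	4	C_C
TRP	N	0	N_DON
TRP	NE1	0	N_DON
TRP	O	1	O_ACC
TRP	OXT	1	O_ACC
TYR	C	5	C_ON
TYR	CA	5	C_ON
TYR	CB	4	C_C
TYR	CD1	4	C_C
TYR	CD2	4	C_C
TYR	CE1	4	C_C
TYR	CE2	4	C_C
TYR	CG	4	C_C
TYR	CZ	5	C_ON
TYR	N	0	N_DON
TYR	O	1	O_ACC
TYR	OH	2	O_DA
TYR	OXT	1	O_ACC
VAL	C	5	C_ON
VAL	CA	5	C_ON
VAL	CB	4	C_C
VAL	CG1	4	C_C
VAL	CG2	4	C_C
VAL	N	0	N_DON
VAL	O	1	O_ACC
VAL	OXT	1	O_ACC
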