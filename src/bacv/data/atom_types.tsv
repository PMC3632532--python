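# residue_name	atom_name	type_label
# 12-type atomic typing of standard-residue heavy atoms (element, heavy-atom
# coordination, bonded hydrogens; '/2+' marks the charged amine class).
ALA	N	N_3H_1
ALA	CA	C_4H_1
ALA	C	C_3(S_2)H_0
ALA	O	O_1H_0
ALA	OXT	O_1H_0-
ALA	CB	C_4H_3
ARG	N	N_3H_1
ARG	CA	C_4H_1
ARG	C	C_3(S_2)H_0
ARG	O	O_1H_0
ARG	OXT	O_1H_0-
ARG	CB	C_4H_2
ARG	CG	C_4H_2
ARG	CD	C_4H_2
ARG	NE	N_3H_1
ARG	CZ	C_3(S_2)H_0
ARG	NH1	N_4H_3/2+
ARG	NH2	N_4H_3/2+
ASN	N	N_3H_1
ASN	CA	C_4H_1
ASN	C	C_3(S_2)H_0
ASN	O	O_1H_0
ASN	OXT	O_1H_0-
ASN	CB	C_4H_2
ASN	CG	C_3(S_2)H_0
ASN	OD1	O_1H_0
ASN	ND2	N_3H_2
ASP	N	N_3H_1
ASP	CA	C_4H_1
ASP	C	C_3(S_2)H_0
ASP	O	O_1H_0
ASP	OXT	O_1H_0-
ASP	CB	C_4H_2
ASP	CG	C_3(S_2)H_0
ASP	OD1	O_1H_0-
ASP	OD2	O_1H_0-
CYS	N	N_3H_1
CYS	CA	C_4H_1
CYS	C	C_3(S_2)H_0
CYS	O	O_1H_0
CYS	OXT	O_1H_0-
CYS	CB	C_4H_2
CYS	SG	C_3(S_2)H_1
GLN	N	N_3H_1
GLN	CA	C_4H_1
GLN	C	C_3(S_2)H_0
GLN	O	O_1H_0
GLN	OXT	O_1H_0-
GLN	CB	C_4H_2
GLN	CG	C_4H_2
GLN	CD	C_3(S_2)H_0
GLN	OE1	O_1H_0
GLN	NE2	N_3H_2
GLU	N	N_3H_1
GLU	CA	C_4H_1
GLU	C	C_3(S_2)H_0
GLU	O	O_1H_0
GLU	OXT	O_1H_0-
GLU	CB	C_4H_2
GLU	CG	C_4H_2
GLU	CD	C_3(S_2)H_0
GLU	OE1	O_1H_0-
GLU	OE2	O_1H_0-
GLY	N	N_3H_1
GLY	CA	C_4H_2
GLY	C	C_3(S_2)H_0
GLY	O	O_1H_0
GLY	OXT	O_1H_0-
HIS	N	N_3H_1
HIS	CA	C_4H_1
HIS	C	C_3(S_2)H_0
HIS	O	O_1H_0
HIS	OXT	O_1H_0-
HIS	CB	C_4H_2
HIS	CG	C_3(S_2)H_0
HIS	ND1	N_3H_0
HIS	CD2	C_3(S_2)H_1
HIS	CE1	C_3(S_2)H_1
HIS	NE2	N_3H_1
ILE	N	N_3H_1
ILE	CA	C_4H_1
ILE	C	C_3(S_2)H_0
ILE	O	O_1H_0
ILE	OXT	O_1H_0-
ILE	CB	C_4H_1
ILE	CG1	C_4H_2
ILE	CG2	C_4H_3
ILE	CD1	C_4H_3
LEU	N	N_3H_1
LEU	CA	C_4H_1
LEU	C	C_3(S_2)H_0
LEU	O	O_1H_0
LEU	OXT	O_1H_0-
LEU	CB	C_4H_2
LEU	CG	C_4H_1
LEU	CD1	C_4H_3
LEU	CD2	C_4H_3
LYS	N	N_3H_1
LYS	CA	C_4H_1
LYS	C	C_3(S_2)H_0
LYS	O	O_1H_0
LYS	OXT	O_1H_0-
LYS	CB	C_4H_2
LYS	CG	C_4H_2
LYS	CD	C_4H_2
LYS	CE	C_4H_2
LYS	NZ	N_4H_3/2+
MET	N	N_3H_1
MET	CA	C_4H_1
MET	C	C_3(S_2)H_0
MET	O	O_1H_0
MET	OXT	O_1H_0-
MET	CB	C_4H_2
MET	CG	C_4H_2
MET	SD	C_3(S_2)H_0
MET	CE	C_4H_3
PHE	N	N_3H_1
PHE	CA	C_4H_1
PHE	C	C_3(S_2)H_0
PHE	O	O_1H_0
PHE	OXT	O_1H_0-
PHE	CB	C_4H_2
PHE	CG	C_3(S_2)H_0
PHE	CD1	C_3(S_2)H_1
PHE	CD2	C_3(S_2)H_1
PHE	CE1	C_3(S_2)H_1
PHE	CE2	C_3(S_2)H_1
PHE	CZ	C_3(S_2)H_1
PRO	N	N_3H_0
PRO	CA	C_4H_1
PRO	C	C_3(S_2)H_0
PRO	O	O_1H_0
PRO	OXT	O_1H_0-
PRO	CB	C_4H_2
PRO	CG	C_4H_2
PRO	CD	C_4H_2
SER	N	N_3H_1
SER	CA	C_4H_1
SER	C	C_3(S_2)H_0
SER	O	O_1H_0
SER	OXT	O_1H_0-
SER	CB	C_4H_2
SER	OG	O_2H_1
THR	N	N_3H_1
THR	CA	C_4H_1
THR	C	C_3(S_2)H_0
THR	O	O_1H_0
THR	OXT	O_1H_0-
THR	CB	C_4H_1
THR	OG1	O_2H_1
THR	CG2	C_4H_3
TRP	N	N_3H_1
TRP	CA	C_4H_1
TRP	C	C_3(S_2)H_0
TRP	O	O_1H_0
TRP	OXT	O_1H_0-
TRP	CB	C_4H_2
TRP	CG	C_3(S_2)H_0
TRP	CD1	C_3(S_2)H_1
TRP	CD2	C_3(S_2)H_0
TRP	NE1	N_3H_1
TRP	CE2	C_3(S_2)H_0
TRP	CE3	C_3(S_2)H_1
TRP	CZ2	C_3(S_2)H_1
TRP	CZ3	C_3(S_2)H_1
TRP	CH2	C_3(S_2)H_1
TYR	N	N_3H_1
TYR	CA	C_4H_1
TYR	C	C_3(S_2)H_0
TYR	O	O_1H_0
TYR	OXT	O_1H_0-
TYR	CB	C_4H_2
TYR	CG	C_3(S_2)H_0
TYR	CD1	C_3(S_2)H_1
TYR	CD2	C_3(S_2)H_1
TYR	CE1	C_3(S_2)H_1
TYR	CE2	C_3(S_2)H_1
TYR	CZ	C_3(S_2)H_0
TYR	OH	O_2H_1
VAL	N	N_3H_1
VAL	CA	C_4H_1
VAL	C	C_3(S_2)H_0
VAL	O	O_1H_0
VAL	OXT	O_1H_0-
VAL	CB	C_4H_1
VAL	CG1	C_4H_3
VAL	CG2	C_4H_3
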