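# res_type	atom_name	classes (comma-separated; empty = no class)
ALA	N	donor
ALA	CA	hydrophobic
ALA	C	
ALA	O	acceptor
ALA	OXT	acceptor,negative
ALA	CB	hydrophobic
ARG	N	donor
ARG	CA	hydrophobic
ARG	C	
ARG	O	acceptor
ARG	OXT	acceptor,negative
ARG	CB	hydrophobic
ARG	CG	hydrophobic
ARG	CD	
ARG	NE	donor,positive
ARG	CZ	
ARG	NH1	donor,positive
ARG	NH2	donor,positive
ASN	N	donor
ASN	CA	hydrophobic
ASN	C	
ASN	O	acceptor
ASN	OXT	acceptor,negative
ASN	CB	hydrophobic
ASN	CG	
ASN	OD1	acceptor
ASN	ND2	donor
ASP	N	donor
ASP	CA	hydrophobic
ASP	C	
ASP	O	acceptor
ASP	OXT	acceptor,negative
ASP	CB	hydrophobic
ASP	CG	
ASP	OD1	acceptor,negative
ASP	OD2	acceptor,negative
CYS	N	donor
CYS	CA	hydrophobic
CYS	C	
CYS	O	acceptor
CYS	OXT	acceptor,negative
CYS	CB	hydrophobic
CYS	SG	donor,acceptor,hydrophobic
GLN	N	donor
GLN	CA	hydrophobic
GLN	C	
GLN	O	acceptor
GLN	OXT	acceptor,negative
GLN	CB	hydrophobic
GLN	CG	hydrophobic
GLN	CD	
GLN	OE1	acceptor
GLN	NE2	donor
GLU	N	donor
GLU	CA	hydrophobic
GLU	C	
GLU	O	acceptor
GLU	OXT	acceptor,negative
GLU	CB	hydrophobic
GLU	CG	hydrophobic
GLU	CD	
GLU	OE1	acceptor,negative
GLU	OE2	acceptor,negative
GLY	N	donor
GLY	CA	hydrophobic
GLY	C	
GLY	O	acceptor
GLY	OXT	acceptor,negative
HIS	N	donor
HIS	CA	hydrophobic
HIS	C	
HIS	O	acceptor
HIS	OXT	acceptor,negative
HIS	CB	hydrophobic
HIS	CG	aromatic
HIS	ND1	aromatic,donor,acceptor
HIS	CD2	aromatic
HIS	CE1	aromatic
HIS	NE2	aromatic,donor,acceptor
ILE	N	donor
ILE	CA	hydrophobic
ILE	C	
ILE	O	acceptor
ILE	OXT	acceptor,negative
ILE	CB	hydrophobic
ILE	CG1	hydrophobic
ILE	CG2	hydrophobic
ILE	CD1	hydrophobic
LEU	N	donor
LEU	CA	hydrophobic
LEU	C	
LEU	O	acceptor
LEU	OXT	acceptor,negative
LEU	CB	hydrophobic
LEU	CG	hydrophobic
LEU	CD1	hydrophobic
LEU	CD2	hydrophobic
LYS	N	donor
LYS	CA	hydrophobic
LYS	C	
LYS	O	acceptor
LYS	OXT	acceptor,negative
LYS	CB	hydrophobic
LYS	CG	hydrophobic
LYS	CD	hydrophobic
LYS	CE	
LYS	NZ	donor,positive
MET	N	donor
MET	CA	hydrophobic
MET	C	
MET	O	acceptor
MET	OXT	acceptor,negative
MET	CB	hydrophobic
MET	CG	hydrophobic
MET	SD	hydrophobic
MET	CE	hydrophobic
PHE	N	donor
PHE	CA	hydrophobic
PHE	C	
PHE	O	acceptor
PHE	OXT	acceptor,negative
PHE	CB	hydrophobic
PHE	CG	aromatic,hydrophobic
PHE	CD1	aromatic,hydrophobic
PHE	CD2	aromatic,hydrophobic
PHE	CE1	aromatic,hydrophobic
PHE	CE2	aromatic,hydrophobic
PHE	CZ	aromatic,hydrophobic
PRO	N	donor
PRO	CA	hydrophobic
PRO	C	
PRO	O	acceptor
PRO	OXT	acceptor,negative
PRO	CB	hydrophobic
PRO	CG	hydrophobic
PRO	CD	
SER	N	donor
SER	CA	hydrophobic
SER	C	
SER	O	acceptor
SER	OXT	acceptor,negative
SER	CB	
SER	OG	donor,acceptor
THR	N	donor
THR	CA	hydrophobic
THR	C	
THR	O	acceptor
THR	OXT	acceptor,negative
THR	CB	
THR	OG1	donor,acceptor
THR	CG2	hydrophobic
TRP	N	donor
TRP	CA	hydrophobic
TRP	C	
TRP	O	acceptor
TRP	OXT	acceptor,negative
TRP	CB	hydrophobic
TRP	CG	aromatic,hydrophobic
TRP	CD1	aromatic
TRP	CD2	aromatic,hydrophobic
TRP	NE1	aromatic,donor
TRP	CE2	aromatic
TRP	CE3	aromatic,hydrophobic
TRP	CZ2	aromatic,hydrophobic
TRP	CZ3	aromatic,hydrophobic
TRP	CH2	aromatic,hydrophobic
TYR	N	donor
TYR	CA	hydrophobic
TYR	C	
TYR	O	acceptor
TYR	OXT	acceptor,negative
TYR	CB	hydrophobic
TYR	CG	aromatic,hydrophobic
TYR	CD1	aromatic,hydrophobic
TYR	CD2	aromatic,hydrophobic
TYR	CE1	aromatic,hydrophobic
TYR	CE2	aromatic,hydrophobic
TYR	CZ	aromatic
TYR	OH	donor,acceptor
VAL	N	donor
VAL	CA	hydrophobic
VAL	C	
VAL	O	acceptor
VAL	OXT	acceptor,negative
VAL	CB	hydrophobic
VAL	CG1	hydrophobic
VAL	CG2	hydrophobic
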