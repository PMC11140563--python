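# Condensed heavy-atom partial charge set (elementary charge units).
# Hydrogen charges are folded into their bonded heavy atom so that structures
# without explicit hydrogens can be scored directly; polarity patterns follow
# the CHARMM36 protein topology. Per-residue sums are exact:
#   0 for neutral residues, +1 for Arg/Lys and protonated His, -1 for Asp/Glu.
# Histidine is tabulated only in its doubly-protonated (+1) form; the assigner
# maps every His to this entry (fixed protonation at formulation pH ~6).
# Columns: residue<TAB>atom<TAB>charge
ALA	N	-0.16
ALA	CA	0.16
ALA	C	0.51
ALA	O	-0.51
ALA	CB	0.00
ARG	N	-0.16
ARG	CA	0.16
ARG	C	0.51
ARG	O	-0.51
ARG	CB	0.00
ARG	CG	0.00
ARG	CD	0.38
ARG	NE	-0.26
ARG	CZ	0.64
ARG	NH1	0.12
ARG	NH2	0.12
ASN	N	-0.16
ASN	CA	0.16
ASN	C	0.51
ASN	O	-0.51
ASN	CB	0.00
ASN	CG	0.55
ASN	OD1	-0.55
ASN	ND2	0.00
ASP	N	-0.16
ASP	CA	0.16
ASP	C	0.51
ASP	O	-0.51
ASP	CB	-0.10
ASP	CG	0.62
ASP	OD1	-0.76
ASP	OD2	-0.76
CYS	N	-0.16
CYS	CA	0.16
CYS	C	0.51
CYS	O	-0.51
CYS	CB	0.07
CYS	SG	-0.07
GLN	N	-0.16
GLN	CA	0.16
GLN	C	0.51
GLN	O	-0.51
GLN	CB	0.00
GLN	CG	0.00
GLN	CD	0.55
GLN	OE1	-0.55
GLN	NE2	0.00
GLU	N	-0.16
GLU	CA	0.16
GLU	C	0.51
GLU	O	-0.51
GLU	CB	0.00
GLU	CG	-0.10
GLU	CD	0.62
GLU	OE1	-0.76
GLU	OE2	-0.76
GLY	N	-0.16
GLY	CA	0.16
GLY	C	0.51
GLY	O	-0.51
HIS	N	-0.16
HIS	CA	0.16
HIS	C	0.51
HIS	O	-0.51
HIS	CB	0.13
HIS	CG	0.19
HIS	ND1	-0.07
HIS	CD2	0.32
HIS	CE1	0.50
HIS	NE2	-0.07
ILE	N	-0.16
ILE	CA	0.16
ILE	C	0.51
ILE	O	-0.51
ILE	CB	0.00
ILE	CG1	0.00
ILE	CG2	0.00
ILE	CD1	0.00
LEU	N	-0.16
LEU	CA	0.16
LEU	C	0.51
LEU	O	-0.51
LEU	CB	0.00
LEU	CG	0.00
LEU	CD1	0.00
LEU	CD2	0.00
LYS	N	-0.16
LYS	CA	0.16
LYS	C	0.51
LYS	O	-0.51
LYS	CB	0.00
LYS	CG	0.00
LYS	CD	0.00
LYS	CE	0.31
LYS	NZ	0.69
MET	N	-0.16
MET	CA	0.16
MET	C	0.51
MET	O	-0.51
MET	CB	0.00
MET	CG	0.04
MET	SD	-0.09
MET	CE	0.05
PHE	N	-0.16
PHE	CA	0.16
PHE	C	0.51
PHE	O	-0.51
PHE	CB	0.00
PHE	CG	0.00
PHE	CD1	0.00
PHE	CD2	0.00
PHE	CE1	0.00
PHE	CE2	0.00
PHE	CZ	0.00
PRO	N	-0.29
PRO	CA	0.11
PRO	C	0.51
PRO	O	-0.51
PRO	CB	0.00
PRO	CG	0.00
PRO	CD	0.18
SER	N	-0.16
SER	CA	0.16
SER	C	0.51
SER	O	-0.51
SER	CB	0.23
SER	OG	-0.23
THR	N	-0.16
THR	CA	0.16
THR	C	0.51
THR	O	-0.51
THR	CB	0.23
THR	OG1	-0.23
THR	CG2	0.00
TRP	N	-0.16
TRP	CA	0.16
TRP	C	0.51
TRP	O	-0.51
TRP	CB	0.00
TRP	CG	-0.03
TRP	CD1	0.15
TRP	NE1	-0.23
TRP	CE2	0.13
TRP	CD2	-0.02
TRP	CE3	0.00
TRP	CZ2	0.00
TRP	CZ3	0.00
TRP	CH2	0.00
TYR	N	-0.16
TYR	CA	0.16
TYR	C	0.51
TYR	O	-0.51
TYR	CB	0.00
TYR	CG	0.00
TYR	CD1	0.00
TYR	CD2	0.00
TYR	CE1	0.00
TYR	CE2	0.00
TYR	CZ	0.11
TYR	OH	-0.11
VAL	N	-0.16
VAL	CA	0.16
VAL	C	0.51
VAL	O	-0.51
VAL	CB	0.00
VAL	CG1	0.00
VAL	CG2	0.00
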