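# Fully-exposed side-chain solvent-accessible surface area (Å²),
# Gly-X-Gly standard-state values after Miller et al. (1987).
# Used as the denominator of the per-residue exposure ratio in SAP scoring.
# Glycine is assigned its alpha-hydrogen patch area so the ratio is defined;
# its SAP contribution is zero regardless (hydrophobicity 0).
# Columns: residue<TAB>sasa
ALA	67.0
ARG	196.0
ASN	113.0
ASP	106.0
CYS	104.0
GLN	144.0
GLU	138.0
GLY	25.0
HIS	151.0
ILE	140.0
LEU	137.0
LYS	167.0
MET	160.0
PHE	175.0
PRO	105.0
SER	80.0
THR	102.0
TRP	217.0
TYR	187.0
VAL	117.0
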