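# Chothia CDR intervals (inclusive; insertion-coded residues whose numeric
# part falls inside an interval belong to it) and variable-region ranges.
# Columns: region<TAB>chain<TAB>start<TAB>end
CDRH1	heavy	26	32
CDRH2	heavy	52	56
CDRH3	heavy	95	102
CDRL1	light	24	34
CDRL2	light	50	56
CDRL3	light	89	97
Hv	heavy	1	113
Lv	light	1	107
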