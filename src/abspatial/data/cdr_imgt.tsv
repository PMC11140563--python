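# IMGT CDR intervals and variable-region ranges.
# Columns: region<TAB>chain<TAB>start<TAB>end
CDRH1	heavy	27	38
CDRH2	heavy	56	65
CDRH3	heavy	105	117
CDRL1	light	27	38
CDRL2	light	56	65
CDRL3	light	105	117
Hv	heavy	1	128
Lv	light	1	127
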