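# Backbone atom names (everything else is side chain).
# Glycine's HA2/HA3 are deliberately absent: they count as side chain so a
# side-chain SASA is defined for Gly (its SAP contribution is still 0).
N
CA
C
O
OXT
H
HN
HA
HA1
H1
H2
H3
HT1
HT2
HT3
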