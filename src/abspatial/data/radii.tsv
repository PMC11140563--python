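# Van der Waals radii by element (Å), Bondi (1964) set.
# Columns: element<TAB>radius
H	1.20
C	1.70
N	1.55
O	1.52
S	1.80
P	1.80
F	1.47
CL	1.75
BR	1.85
I	1.98
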