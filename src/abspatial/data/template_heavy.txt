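# Chothia heavy-chain slot template, one slot label per line in
# sequence order; 145 slots total. Insertion slots sit at the CDR
# loops; CDRH3 (95-102 plus 100A-100V) holds at most 30 residues.
1
2
3
4
5
6
7
8
9
10
11
12
13
14
15
16
17
18
19
20
21
22
23
24
25
26
27
28
29
30
31
31A
31B
31C
31D
31E
32
33
34
35
36
37
38
39
40
41
42
43
44
45
46
47
48
49
50
51
52
52A
52B
52C
53
54
55
56
57
58
59
60
61
62
63
64
65
66
67
68
69
70
71
72
73
74
75
76
77
78
79
80
81
82
82A
82B
83
84
85
86
87
88
89
90
91
92
93
94
95
96
97
98
99
100
100A
100B
100C
100D
100E
100F
100G
100H
100I
100J
100K
100L
100M
100N
100O
100P
100Q
100R
100S
100T
100U
100V
101
102
103
104
105
106
107
108
109
110
111
112
113
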