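# Chothia light-chain slot template, one slot label per line in
# sequence order; 127 slots total.
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
27A
27B
27C
27D
27E
27F
28
29
30
31
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
52D
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
95A
95B
95C
95D
95E
95F
95G
95H
95I
95J
96
97
98
99
100
101
102
103
104
105
106
107
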