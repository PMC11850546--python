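# Default HLA-DRB1 beta-chain peptide-contact positions (editable).
# Derived with the 4 A heavy-atom contact rule from peptide-bound class II
# structures; override with any position list of the same CSV shape.
position
9
11
13
26
28
30
32
37
38
47
56
57
60
61
67
70
71
74
77
78
81
82
85
86
89
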