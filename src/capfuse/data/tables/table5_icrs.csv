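case,assessor2,assessor3,intraop
1,II,II,II
2,III,III,III
3,IV,IV,IV
4,IV,IV,IV
5,III,III,III
6,IV,IV,IV
7,IV,IV,IV
8,III,III,III
9,III,III,III
10,IV,IV,IV
11,IV,IV,IV
12,III,III,III
13,III,III,III
14,III,III,III
15,III,III,IV
16,III,III,III
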