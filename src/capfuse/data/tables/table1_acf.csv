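case,mcfi_areas,op_areas
1,1,1
2,1;2;3;4,1;2;3;4
3,,
4,2,2
5,1;2;3,1;2;3
6,,
7,2,2
8,2;3,2;3
9,1;3;4,1;3;4
10,1;4,1;4
11,1,1
12,1;2;3;4,1;2;3;4
13,2;3,2;3
14,2;3,2;3
15,1;2;3;4,1;2;3;4
16,2;3,2;3
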