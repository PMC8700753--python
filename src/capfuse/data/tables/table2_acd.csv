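case,mcfi_areas,op_areas,op_detached
1,,,false
2,,,false
3,2;3,2;3,false
4,2;3,2;3,false
5,,,false
6,2,2,false
7,2;3,2;3,false
8,,,false
9,,,false
10,1,1,false
11,1,1,false
12,,,false
13,,,false
14,,,false
15,,1;2;3;4,true
16,,,false
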