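case,mcfi_areas,mcfi_subtype,op_areas,op_subtype,op_detached
1,,,,,false
2,2;3,protrusion,2;3,protrusion,false
3,,,,,false
4,,,,,false
5,2;3,protrusion,2;3,protrusion,false
6,,,,,false
7,,,,,false
8,2;3,protrusion,2;3,protrusion,false
9,2;3,protrusion,2;3,protrusion,false
10,1;2;3;4,flattening,1;2;3;4,flattening,false
11,1;2;3;4,flattening,1;2;3;4,flattening,false
12,2;3,protrusion,2;3,protrusion,false
13,2;3,protrusion,2;3,protrusion,false
14,2;3,protrusion,2;3,protrusion,false
15,1;2;3;4,protrusion,1;2;3;4,,true
16,2;3,protrusion,2;3,protrusion,false
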