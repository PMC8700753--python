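case,mcfi_vertical,op_vertical,mcfi_horizontal,op_horizontal
1,,,,
2,19.7,18,12.3,12
3,7.9,8,11.5,11
4,13.6,12,14.5,14
5,16.1,14,15.6,15
6,11.6,10,8.8,8
7,12.1,15,14.3,13
8,18.7,17,12.5,12
9,19.4,19,14.1,14
10,16.9,16,14.7,12
11,19.5,20,16,15
12,16,18,12,12
13,11.6,11,7.8,8
14,14.8,14,11.8,10
15,13.5,13,14.2,11
16,12.5,12,13.1,10
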