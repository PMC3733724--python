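,A,B,C,D,E,F
A,6,4,0,0,0,0
B,4,56,11,0,0,0
C,0,16,50,13,0,0
D,0,0,14,102,9,0
E,0,0,0,14,48,6
F,0,0,0,0,3,19
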