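,N1,P1,P2,DY
N1,12,9,0,0
P1,4,139,13,5
P2,0,7,101,14
DY,0,2,13,56
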