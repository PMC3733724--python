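,Certain,Probable,Possible,No
Certain,5,3,0,0
Probable,3,11,4,0
Possible,2,13,3,4
No,1,2,4,14
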