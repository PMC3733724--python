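,AEF,SFD,HD,ED
AEF,147,13,0,0
SFD,14,101,10,0
HD,0,14,48,6
ED,0,0,3,19
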