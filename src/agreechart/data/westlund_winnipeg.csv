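,Certain,Probable,Possible,No
Certain,38,5,0,1
Probable,33,11,3,0
Possible,10,14,5,6
No,3,7,3,10
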