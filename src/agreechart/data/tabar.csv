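,II,III,IV,V
II,12,9,0,0
III,4,170,16,8
IV,0,4,114,6
V,0,8,9,15
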