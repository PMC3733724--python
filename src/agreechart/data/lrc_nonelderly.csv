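,CVD,Non-CVD
CVD,122,10
Non-CVD,5,18
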