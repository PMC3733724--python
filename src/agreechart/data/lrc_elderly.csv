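,CVD,Non-CVD
CVD,172,11
Non-CVD,35,50
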