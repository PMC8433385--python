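label,slope
AHS_0.1,0.728
AHS_0.3,0.168
AHS_0.6,0.075
AHS_0.9,0.043
AHS_1.2,0.016
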