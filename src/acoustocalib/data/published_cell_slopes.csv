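label,slope
MDA-MB-231,0.209
MCF-7,0.099
SKBR-3,0.090
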