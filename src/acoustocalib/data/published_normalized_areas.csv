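group,pressure_mpa,normalized_area
MDA-MB-231,0.000,1.000
MDA-MB-231,0.234,1.025
MDA-MB-231,0.431,1.085
MDA-MB-231,0.627,1.130
MDA-MB-231,0.824,1.173
MDA-MB-231,1.000,1.194
MCF-7,0.000,1.000
MCF-7,0.234,1.015
MCF-7,0.431,1.041
MCF-7,0.627,1.061
MCF-7,0.824,1.084
MCF-7,1.000,1.090
SKBR-3,0.000,1.000
SKBR-3,0.234,1.015
SKBR-3,0.431,1.033
SKBR-3,0.627,1.055
SKBR-3,0.824,1.071
SKBR-3,1.000,1.088
AHS_0.1,0.000,1.000
AHS_0.1,0.234,1.211
AHS_0.1,0.431,1.312
AHS_0.3,0.000,1.000
AHS_0.3,0.234,1.061
AHS_0.3,0.431,1.102
AHS_0.3,0.627,1.123
AHS_0.3,0.824,1.154
AHS_0.3,1.000,1.173
AHS_0.6,0.000,1.000
AHS_0.6,0.234,1.048
AHS_0.6,0.431,1.067
AHS_0.6,0.627,1.068
AHS_0.6,0.824,1.077
AHS_0.6,1.000,1.084
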