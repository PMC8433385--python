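label,E_kpa,E_sd_kpa
AHS_0.1,0.214,0.082
AHS_0.3,1.603,0.242
AHS_0.6,2.995,0.573
AHS_0.9,6.401,1.089
AHS_1.2,9.235,1.634
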