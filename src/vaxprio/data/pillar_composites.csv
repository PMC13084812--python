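vaccine,importance,feasibility,combined
hpv,2.8,2.0,2.5
pcv_hr,3.2,3.3,3.2
flu_hr,3.7,3.2,3.5
varicella,3.6,4.3,3.8
tdap,4.1,3.4,3.9
rsv,3.6,4.8,4.0
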