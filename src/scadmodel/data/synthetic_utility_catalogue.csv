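sex,age_lo,age_hi,base_utility,condition_multiplier,acute_multiplier,mult_post_mi,mult_post_is,mult_post_hs
male,18,24,0.94,0.92,0.85,0.88,0.8,0.75
male,25,34,0.93,0.92,0.85,0.88,0.8,0.75
male,35,44,0.91,0.92,0.85,0.88,0.8,0.75
male,45,54,0.85,0.92,0.85,0.88,0.8,0.75
male,55,64,0.8,0.92,0.85,0.88,0.8,0.75
male,65,74,0.78,0.92,0.85,0.88,0.8,0.75
male,75,110,0.73,0.92,0.85,0.88,0.8,0.75
female,18,24,0.9199999999999999,0.92,0.85,0.88,0.8,0.75
female,25,34,0.91,0.92,0.85,0.88,0.8,0.75
female,35,44,0.89,0.92,0.85,0.88,0.8,0.75
female,45,54,0.83,0.92,0.85,0.88,0.8,0.75
female,55,64,0.78,0.92,0.85,0.88,0.8,0.75
female,65,74,0.76,0.92,0.85,0.88,0.8,0.75
female,75,110,0.71,0.92,0.85,0.88,0.8,0.75
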