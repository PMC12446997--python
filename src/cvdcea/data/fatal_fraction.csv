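sex,event,intercept,age_slope
male,mi,-4.30,0.042
female,mi,-4.60,0.042
male,stroke,-4.80,0.045
female,stroke,-4.90,0.045
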