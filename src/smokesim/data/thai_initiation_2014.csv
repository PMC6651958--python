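sex,age_group,initiation
male,15-19,0.050
male,20-24,0.027
male,25-29,0.008
male,30+,0.001
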