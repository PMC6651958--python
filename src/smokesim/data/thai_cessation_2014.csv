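sex,age_group,cessation
male,15-19,0.033
male,20-24,0.014
male,25-29,0.015
male,30-34,0.013
male,35-39,0.022
male,40-44,0.022
male,45-49,0.030
male,50-54,0.038
male,55-59,0.061
male,60-64,0.048
male,65-69,0.061
male,70-74,0.074
male,75+,0.136
male,all_ages,0.033
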