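sex,age_group,p_never,p_current,p_former
male,15-19,79.1,19.4,1.4
male,20-24,54.2,41.5,4.3
male,25-29,41.9,51.3,6.8
male,30-34,47.4,46.4,6.3
male,35-39,44.7,46.9,8.4
male,40-44,43.7,45.0,11.3
male,45-49,40.1,48.4,11.5
male,50-54,41.4,41.2,17.4
male,55-59,41.0,41.8,17.2
male,60-64,35.4,38.7,25.9
male,65-69,36.4,33.8,29.8
male,70-74,38.9,32.3,28.7
male,75+,41.1,23.4,35.6
male,overall,46.7,40.5,12.8
female,15-19,99.2,0.3,0.5
female,20-24,98.6,0.2,1.2
female,25-29,98.7,0.9,0.4
female,30-34,98.4,1.3,0.4
female,35-39,97.3,1.8,0.9
female,40-44,96.7,2.3,1.0
female,45-49,96.8,2.9,0.3
female,50-54,96.1,3.1,0.8
female,55-59,94.3,4.2,1.5
female,60-64,94.7,3.3,2.0
female,65-69,94.0,3.3,2.8
female,70-74,96.0,1.4,2.7
female,75+,91.9,4.1,4.0
female,overall,96.7,2.1,1.2
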