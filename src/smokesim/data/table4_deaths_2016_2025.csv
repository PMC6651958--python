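year,baseline_all_cause,youth_access,tax,quit_line,brief_advice,combined
2016,256947,0,0,0,0,0
2017,248268,0,0,0,0,0
2018,240143,78,0,78,640,811
2019,232517,223,116,206,1686,2290
2020,225346,425,423,366,2982,4332
2021,218591,674,967,545,4426,6856
2022,212219,963,1776,734,5950,9804
2023,206200,1286,2866,930,7507,13127
2024,200505,1634,4244,1126,9069,16790
2025,195115,2001,5909,1320,10612,20759
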