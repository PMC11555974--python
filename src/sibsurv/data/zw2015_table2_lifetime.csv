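# Worked example: sisters reaching age 15 and sisters surviving, by respondent
# age group, 2015 Zimbabwe DHS (adult lifetime-proportions method input).
n,age_group,reached15,surviving
25,20-24,2580,2441
30,25-29,3370,3055
35,30-34,3787,3361
40,35-39,3110,2648
45,40-44,2578,2074
50,45-49,1543,1145
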