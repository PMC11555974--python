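# Worked example: proportions of adult sisters alive 5 years before the survey
# (s_tm5) and at the survey (s_t), by respondent age group, 2015 Zimbabwe DHS.
n,age_group,s_tm5,s_t
15,15-19,0.982,0.963
20,20-24,0.968,0.946
25,25-29,0.936,0.906
30,30-34,0.914,0.887
35,35-39,0.883,0.851
40,40-44,0.843,0.805
45,45-49,0.787,0.742
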