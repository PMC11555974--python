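# Worked example: proportions of adult sisters still alive at each survey, by
# respondent age group, Zimbabwe 2010-11 and 2015 DHS. The 2015 column is
# tabulated on the cohorts matching the 2010-11 age groups (aged n-0.24 at the
# second survey); the inter-survey interval is 4.76 years.
n,age_group,s_survey1,s_survey2
15,15-19,0.957,0.962
20,20-24,0.929,0.946
25,25-29,0.910,0.908
30,30-34,0.887,0.889
35,35-39,0.832,0.853
40,40-44,0.802,0.805
45,45-49,0.774,0.741
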