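# Worked example: female deaths and person-years by age group from the full
# sibling histories of the 2015 Zimbabwe DHS, for two reference windows.
window_years,n,age_group,deaths,person_years
7,15,15-19,30,15812
7,20,20-24,49,19840
7,25,25-29,113,22540
7,30,30-34,212,19692
7,35,35-39,180,13168
7,40,40-44,123,8046
7,45,45-49,83,4831
5,15,15-19,23,10590
5,20,20-24,32,13645
5,25,25-29,72,15908
5,30,30-34,141,14942
5,35,35-39,108,10054
5,40,40-44,85,6270
5,45,45-49,50,3699
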