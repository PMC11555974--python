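# Brass general standard survivorship, radix 1, as tabulated with the
# relational logit life-table system (ages 1-4 single years, then quinquennial).
age,lx
0,1.0000
1,0.8499
2,0.8070
3,0.7876
4,0.7762
5,0.7691
10,0.7502
15,0.7362
20,0.7130
25,0.6826
30,0.6525
35,0.6223
40,0.5898
45,0.5535
50,0.5106
55,0.4585
60,0.3965
65,0.3210
70,0.2380
75,0.1516
80,0.0768
85,0.0276
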