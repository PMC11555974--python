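# Published conversion coefficients for the adult lifetime-proportions sibling
# method (Timaeus-Zaba-Ali): n-15 p 15 = beta0(n) + beta1(n) * 5S(15+)(n-5),
# where respondents are aged n-5 to n.
method,n,age_group,beta0,beta1
eq3_lifetime,25,20-24,-0.0003,1.0011
eq3_lifetime,30,25-29,-0.1546,1.1560
eq3_lifetime,35,30-34,-0.1645,1.1660
eq3_lifetime,40,35-39,-0.1388,1.1406
eq3_lifetime,45,40-44,-0.1140,1.1168
eq3_lifetime,50,45-49,-0.1018,1.1066
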