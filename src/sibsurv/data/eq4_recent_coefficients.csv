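# Published conversion coefficients for the recent-deaths summary sibling
# method: 5pn = beta0(n) + beta1(n) * S(t)/S(t-5), per respondent age group.
# r_squared and cv are the published fit diagnostics (reporting only).
method,n,age_group,beta0,beta1,r_squared,cv
eq4_recent,15,15-19,0.0535,0.9459,0.9200,0.0039
eq4_recent,20,20-24,-0.2408,1.2404,0.9323,0.0049
eq4_recent,25,25-29,-0.0752,1.0742,0.9320,0.0050
eq4_recent,30,30-34,0.0169,0.9829,0.9116,0.0055
eq4_recent,35,35-39,0.0151,0.9843,0.9002,0.0067
eq4_recent,40,40-44,-0.0273,1.0268,0.9061,0.0078
eq4_recent,45,45-49,-0.0332,1.0326,0.9126,0.0086
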