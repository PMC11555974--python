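# Recent-deaths conversion coefficients REGENERATED by this package's own
# stable-population simulation study (192 parameter combinations x 2 seeds,
# target final size 16,000; regenerate with scripts/refit_coefficients.py
# --full).  Differences from the published set reflect the synthetic
# fertility standard used here.
method,n,age_group,beta0,beta1,r_squared,cv
eq4_recent_refit,15,15-19,-0.031095,1.031856,0.965107,0.002442
eq4_recent_refit,20,20-24,-0.234652,1.23494,0.979139,0.002519
eq4_recent_refit,25,25-29,-0.117043,1.117333,0.980324,0.002485
eq4_recent_refit,30,30-34,-0.017697,1.017967,0.978586,0.002677
eq4_recent_refit,35,35-39,-0.002582,1.002811,0.979518,0.002912
eq4_recent_refit,40,40-44,-0.045077,1.046811,0.974745,0.003758
eq4_recent_refit,45,45-49,-0.053463,1.055269,0.973345,0.004798
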