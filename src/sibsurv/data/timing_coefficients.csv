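# Time location of lifetime-method estimates: years before the survey
# T(n) = c0 + c1*ln(5S), fitted across the package's stable-population
# simulation grid (regenerate with scripts/fit_timing.py).
n,c0,c1,n_points
25,12.650609614934458,0.0,40
30,11.097865215212433,0.0,39
35,10.255629738380804,0.0,40
40,11.318657575299545,0.0,42
45,13.229081231607216,0.0,43
50,15.628166824295812,0.0,44
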