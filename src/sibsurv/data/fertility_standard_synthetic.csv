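# SYNTHETIC high-fertility standard schedule for the relational Gompertz model.
# Built on the natural-fertility age pattern (broad peak in the early-to-mid
# twenties, long upper tail, mean age ~28.5 years); it stands in for a published
# high-fertility standard and is labelled synthetic accordingly. Rates are
# births per woman-year for the 5-year group starting at `age`; the absolute
# level is a free scale in the relational model.
age,rate
15,0.300
20,0.470
25,0.440
30,0.385
35,0.290
40,0.140
45,0.020
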