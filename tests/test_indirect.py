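"""Indirect estimators: lifetime, recent-deaths, two-survey."""

import numpy as np
import pandas as pd
import pytest

from sibsurv.coefficients import CoefficientTable, SummaryTabulation, tabulate_summary
from sibsurv.indirect import (
    LifetimeInput,
    TwoSurveyInput,
    awkward_interval_adjust,
    estimate_gompertz_slope,
    indirect_ci,
    lifetime_method,
    recent_method,
    two_survey_method,
)


def _identity_lifetime_coefs():
    ns = list(range(25, 55, 5))
    return CoefficientTable(
        pd.DataFrame({"n": ns, "age_group": [f"{n-5}-{n-1}" for n in ns],
                      "beta0": 0.0, "beta1": 1.0}),
        "eq3_lifetime",
    )


class TestLifetimeMethod:
    def test_full_survival_maps_to_zero_mortality(self):
        table = pd.DataFrame({"n": [25], "age_group": ["20-24"],
                              "reached15": [100.0], "surviving": [100.0]})
        est = lifetime_method(LifetimeInput(table=table),
                              coef=_identity_lifetime_coefs())
        assert est.by_age.p15_n.iloc[0] == 1.0
        assert est.by_age.q35_15.iloc[0] == 0.0

    def test_under_twenty_reports_are_dropped(self):
        table = pd.DataFrame({"n": [20, 25], "age_group": ["15-19", "20-24"],
                              "reached15": [50.0, 100.0],
                              "surviving": [45.0, 95.0]})
        est = lifetime_method(LifetimeInput(table=table))
        assert list(est.by_age.n) == [25]
        assert est.by_age.attrs["dropped_age_groups"] == ["15-19"]

    def test_survivors_cannot_exceed_reaching(self):
        with pytest.raises(ValueError):
            LifetimeInput(table=pd.DataFrame(
                {"n": [25], "age_group": ["20-24"],
                 "reached15": [10.0], "surviving": [11.0]}))

    def test_summary_is_mean_of_20s_respondents(self, table2):
        est = lifetime_method(LifetimeInput(table=table2))
        young = est.by_age[est.by_age.n.isin([25, 30])]
        assert est.q35_15 == pytest.approx(young.q35_15.mean())


class TestAwkwardInterval:
    def test_five_year_interval_is_identity(self):
        r = np.array([0.91, 0.97, 0.995])
        np.testing.assert_array_equal(awkward_interval_adjust(r, 5.0), r)

    @pytest.mark.parametrize("T", [3.5, 4.0, 4.76])
    def test_shorter_interval_lowers_the_ratio(self, T):
        for ratio in np.linspace(0.85, 0.999, 12):
            adj = awkward_interval_adjust(ratio, T)
            assert adj <= ratio

    def test_longer_interval_raises_the_ratio(self):
        assert awkward_interval_adjust(0.95, 7.0) > 0.95

    def test_unsupported_interval_refused(self):
        with pytest.raises(ValueError, match="3-8"):
            awkward_interval_adjust(0.95, 12.0)

    def test_zero_ratio_rejected(self):
        with pytest.raises(ValueError):
            awkward_interval_adjust(0.0, 4.0)

    def test_slope_estimate_recovers_generating_gradient(self):
        ns = np.arange(15, 50, 5)
        beta = 0.04
        ratios = np.exp(-0.002 * np.exp(beta * (ns + 2.5)))
        assert estimate_gompertz_slope(ns, ratios) == pytest.approx(beta, abs=1e-6)


class TestRecentAndTwoSurveyEquivalence:
    def test_equal_at_five_year_interval(self, small_full_ssh):
        tab = tabulate_summary(small_full_ssh)
        est_recent = recent_method(tab, sex="f")
        rows = tab.for_sex("f").set_index("n")
        inp = TwoSurveyInput(
            survey1=pd.Series({n - 5: rows.s_tm5[n] for n in rows.index}),
            survey2=pd.Series({n: rows.s_t[n] for n in rows.index}),
            interval_years=5.0,
        )
        est_two = two_survey_method(inp)
        np.testing.assert_allclose(est_two.by_age.p5, est_recent.by_age.p5,
                                   atol=1e-12)
        assert est_two.q35_15 == pytest.approx(est_recent.q35_15, abs=1e-12)

    def test_identical_surveys_without_deaths_give_near_zero(self):
        s = pd.Series({n: 0.95 for n in range(15, 50, 5)})
        est = two_survey_method(
            TwoSurveyInput(survey1=pd.Series({n - 5: 0.95 for n in s.index}),
                           survey2=s, interval_years=5.0)
        )
        assert np.allclose(est.by_age.raw_ratio[1:], 1.0)
        assert est.q35_15 < 0.01

    def test_all_recent_deaths_zero_gives_near_zero_mortality(self, small_full_ssh):
        df = small_full_ssh.copy()
        v = df.interview_cmc.iloc[0]
        old = df.sib_death_cmc.notna() & (df.sib_death_cmc >= v - 60)
        df.loc[old, "sib_death_cmc"] = v - 100  # push deaths out of the window
        est = recent_method(tabulate_summary(df), sex="f")
        assert np.allclose(est.by_age.ratio, 1.0)
        assert est.q35_15 < 0.01


class TestWeightInvariance:
    def test_uniform_rescaling_changes_no_estimator(self, small_full_ssh):
        scaled = small_full_ssh.assign(weight=small_full_ssh.weight * 7.5)
        for df in (small_full_ssh, scaled):
            df.attrs = {}
        a = recent_method(tabulate_summary(small_full_ssh), sex="f")
        b = recent_method(tabulate_summary(scaled), sex="f")
        np.testing.assert_allclose(a.by_age.p5, b.by_age.p5, atol=1e-12)

        t1 = tabulate_summary(small_full_ssh).for_sex("both")
        lt_in = LifetimeInput(table=pd.DataFrame(
            {"n": t1.n + 5, "age_group": t1.age_group,
             "reached15": t1.reached15, "surviving": t1.reached15 - t1.died}))
        lt_in2 = LifetimeInput(table=lt_in.table.assign(
            reached15=lt_in.table.reached15 * 7.5,
            surviving=lt_in.table.surviving * 7.5))
        ea, eb = lifetime_method(lt_in), lifetime_method(lt_in2)
        np.testing.assert_allclose(ea.by_age.p15_n, eb.by_age.p15_n, atol=1e-12)


class TestIndirectCI:
    def test_homogeneous_clusters_give_zero_width(self, small_full_ssh):
        df = small_full_ssh.copy()
        base = df[df.cluster == df.cluster.iloc[0]].copy()
        clones = []
        for c in range(5):
            clone = base.copy()
            clone["cluster"] = c
            clones.append(clone)
        df = pd.concat(clones, ignore_index=True)
        est = indirect_ci(df, sex="f")
        lo, hi = est.q35_15_ci
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_jackknife_ci_brackets_estimate(self, small_full_ssh):
        est = indirect_ci(small_full_ssh, sex="f")
        lo, hi = est.q35_15_ci
        assert lo < est.q35_15 < hi

    def test_binomial_ci_same_order_of_magnitude(self, small_full_ssh):
        jk = indirect_ci(small_full_ssh, sex="f", method="jackknife")
        bn = indirect_ci(small_full_ssh, sex="f", method="binomial")
        w_jk = jk.q35_15_ci[1] - jk.q35_15_ci[0]
        w_bn = bn.q35_15_ci[1] - bn.q35_15_ci[0]
        assert 0.2 < w_bn / w_jk < 5.0
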