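"""Indirect adult-mortality estimators from summary sibling tabulations.

Three estimators are provided:

``lifetime_method``
    Adult lifetime proportions: the proportion of siblings who reached age 15
    that are still alive at the survey, per respondent age group, converted
    into the life-table survivorship n-15p15 with published linear
    coefficients, then into 35q15 through a model life-table family.  Each
    age group's estimate refers to a different period before the survey
    (older respondents' siblings died longer ago); a time-location table
    derived from the package's own stable-population simulations dates them.

``recent_method``
    The recent-deaths estimator: the ratio S(t)/S(t-5) of the proportions of
    adult siblings alive at the survey and five years earlier (reconstructed
    from the "deaths in the last 5 years" question) is converted into 5pn
    per age group with the packaged conversion coefficients and chained into
    35q15 for the five years before the survey.

``two_survey_method``
    The same synthetic-cohort logic applied to two successive surveys about
    five years apart: the change in a respondent cohort's proportion of
    adult siblings alive between the surveys plays the role of the ratio.
    When the inter-survey interval T differs from five years the ratio is
    first converted to a five-year basis under the Gompertz assumption that
    the adult force of mortality grows exponentially in age with slope
    ``gompertz_slope`` (see :func:`awkward_interval_adjust`).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from sibsurv.coefficients import (
    CoefficientTable,
    SummaryTabulation,
    apply_coefficients,
    tabulate_summary,
)
from sibsurv.direct import jackknife_se
from sibsurv.schedules import chain_35q15, west_model_lookup
from scipy import stats

__all__ = [
    "LifetimeInput",
    "TwoSurveyInput",
    "IndirectEstimates",
    "lifetime_method",
    "recent_method",
    "awkward_interval_adjust",
    "estimate_gompertz_slope",
    "two_survey_method",
    "indirect_ci",
    "load_timing_table",
]

DEFAULT_GOMPERTZ_SLOPE = 0.1  # per year of age


@dataclass(frozen=True)
class LifetimeInput:
    """Per-age-group counts for the adult lifetime-proportions method.

    ``table`` columns: n (= upper bound of the respondent group + 5, the
    convention of the coefficient tables: respondents aged n-5..n inform
    survivorship to age n-10... see ``lifetime_method``), age_group,
    reached15, surviving.
    """

    table: pd.DataFrame
    sex: str = "f"
    survey_time: float | None = None

    def __post_init__(self):
        if (self.table["surviving"] > self.table["reached15"] + 1e-9).any():
            raise ValueError("survivors cannot exceed siblings reaching 15")


@dataclass(frozen=True)
class TwoSurveyInput:
    """Proportions of adult siblings alive at two successive surveys.

    ``survey1``/``survey2`` map age-group lower bound n to the proportion
    5S(15+) for respondents aged n..n+4 at that survey; ``interval_years``
    is the inter-survey gap T.  In ``survey2`` the proportions should be
    tabulated on the cohorts matching the first survey's age groups (i.e.
    respondents aged n-T+5 .. n+4-T+5 at the second survey, labelled by n).
    """

    survey1: pd.Series
    survey2: pd.Series
    interval_years: float
    sex: str = "f"

    def __post_init__(self):
        for s in (self.survey1, self.survey2):
            if ((s <= 0) | (s > 1)).any():
                raise ValueError("proportions must be in (0, 1]")


@dataclass
class IndirectEstimates:
    """Output of an indirect estimator."""

    by_age: pd.DataFrame
    q35_15: float | None
    method: str
    reference_period: str
    q35_15_ci: tuple[float, float] | None = None
    ci: pd.DataFrame | None = field(default=None, repr=False)


@dataclass(frozen=True)
class TimingTable:
    """Time location of lifetime-method estimates, per age group.

    T(n) = c0(n) + c1(n) * ln(5S(15+)) years before the survey, with
    coefficients fitted across the package's stable-population simulation
    grid (see scripts/fit_timing.py).
    """

    table: pd.DataFrame

    def years_before_survey(self, n: int, s: float) -> float:
        row = self.table[self.table["n"] == int(n)]
        if row.empty:
            return float("nan")
        return float(row["c0"].iloc[0] + row["c1"].iloc[0] * np.log(s))


def load_timing_table() -> TimingTable:
    text = resources.files("sibsurv.data").joinpath("timing_coefficients.csv").read_text()
    return TimingTable(pd.read_csv(_io.StringIO(text), comment="#"))


def lifetime_method(
    inp: LifetimeInput,
    coef: CoefficientTable | None = None,
    timing: TimingTable | None = None,
) -> IndirectEstimates:
    """Adult lifetime-proportions estimator.

    Respondents aged n-5..n report the proportion 5S(15+) of their adult
    siblings still alive; survivorship n-15p15 = beta0(n) + beta1(n)*S is
    then translated into 35q15 with the model life-table family.  Reports
    from respondents aged 15-19 are discarded (their siblings are on average
    older than they are, which makes the conversion unstable); if present
    they are dropped with a warning entry in ``by_age.attrs``.
    """
    coef = coef or CoefficientTable.published_lifetime()
    if timing is None:
        try:
            timing = load_timing_table()
        except FileNotFoundError:
            timing = None
    t = inp.table.copy().sort_values("n").reset_index(drop=True)
    dropped = t[t["n"] < 25]
    t = t[t["n"] >= 25].reset_index(drop=True)
    t["s_lifetime"] = t["surviving"] / t["reached15"]
    p15, q35, years, extrap = [], [], [], []
    for _, row in t.iterrows():
        b0, b1 = coef.lookup(row["n"])
        p = float(np.clip(b0 + b1 * row["s_lifetime"], 0.0, 1.0))
        p15.append(p)
        if p >= 1.0:
            q35.append(0.0)
            extrap.append(True)
        else:
            q, fl = west_model_lookup(p, sex="female" if inp.sex == "f" else "male",
                                      n=int(row["n"]))
            q35.append(q)
            extrap.append(fl)
        years.append(
            timing.years_before_survey(int(row["n"]), float(row["s_lifetime"]))
            if timing is not None else float("nan")
        )
    t["p15_n"] = p15
    t["q35_15"] = q35
    t["years_before_survey"] = years
    t["extrapolated"] = extrap
    if len(dropped):
        t.attrs["dropped_age_groups"] = dropped["age_group"].tolist()
    sel = t["n"].isin([25, 30])
    avg = float(t.loc[sel, "q35_15"].mean()) if sel.any() else None
    return IndirectEstimates(
        by_age=t,
        q35_15=avg,
        method="lifetime",
        reference_period="3-15 years before the survey (per age group)",
    )


def recent_method(
    tab: SummaryTabulation,
    coef: CoefficientTable | None = None,
    sex: str = "f",
) -> IndirectEstimates:
    """Recent-deaths estimator: S(t)/S(t-5) ratios -> 5pn -> chained 35q15."""
    coef = coef or CoefficientTable.published_recent()
    conv = apply_coefficients(tab, coef, sex=sex)
    conv = conv.sort_values("n").reset_index(drop=True)
    q35 = chain_35q15(conv["p5"].to_numpy(), expected_groups=None) \
        if len(conv) != 7 else chain_35q15(conv["p5"].to_numpy())
    return IndirectEstimates(
        by_age=conv,
        q35_15=q35,
        method="recent",
        reference_period="0-4 years before the survey",
    )


def awkward_interval_adjust(
    ratio,
    interval_years: float,
    gompertz_slope: float = DEFAULT_GOMPERTZ_SLOPE,
):
    """Convert a T-year cohort survival ratio to its 5-year equivalent.

    Under a Gompertz force of mortality mu(x) = a*exp(beta*x), survival of
    the same cohort from the same starting age over 5 instead of T years
    satisfies ln p5 = ln pT * (e^{5 beta} - 1)/(e^{T beta} - 1), which is the
    identity at T = 5 and lowers the ratio when T < 5 (five years of exposure
    kill more than T).  ``ratio`` may be a scalar or an array.
    """
    if not 3.0 <= interval_years <= 8.0:
        raise ValueError("inter-survey intervals outside 3-8 years are not supported")
    r = np.asarray(ratio, dtype=float)
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("survival ratios must be in (0, 1]")
    if interval_years == 5.0:
        out = r
    else:
        b = gompertz_slope
        k = np.expm1(5.0 * b) / np.expm1(interval_years * b)
        out = np.exp(np.log(r) * k)
    return float(out) if out.ndim == 0 else out


def estimate_gompertz_slope(ns, ratios, fallback: float = 0.05) -> float:
    """Slope of the sibling-set log-hazard in age, from the ratios themselves.

    Regresses ln(-ln ratio) on the age-group midpoints; the ratios measure
    the sibling sets' survival over the inter-survey window, so the fitted
    slope is the operative Gompertz beta for those aggregates (flatter than
    an individual's because each set mixes a wide span of sibling ages).
    Returns ``fallback`` when fewer than three informative age groups exist,
    and clips to [0, 0.15].
    """
    ns = np.asarray(ns, dtype=float)
    r = np.asarray(ratios, dtype=float)
    ok = (r > 0) & (r < 1)
    if ok.sum() < 3:
        return fallback
    x = ns[ok] + 2.5
    y = np.log(-np.log(r[ok]))
    slope = np.polyfit(x, y, 1)[0]
    return float(np.clip(slope, 0.0, 0.15))


def two_survey_method(
    inp: TwoSurveyInput,
    coef: CoefficientTable | None = None,
    gompertz_slope: float | None = None,
) -> IndirectEstimates:
    """Two-survey cohort-change estimator.

    For each age group n of the *second* survey, the cohort ratio is
    S2(n) / S1(n-5): the same respondent cohort observed T years apart.  The
    youngest group's denominator defaults to 1 when the first survey has no
    matching (under-15) cohort.  Ratios are adjusted to a 5-year basis and
    converted exactly as in the recent-deaths method.  When ``gompertz_slope``
    is None the slope is estimated from the input's own age gradient with
    :func:`estimate_gompertz_slope`.
    """
    coef = coef or CoefficientTable.published_recent()
    ns = sorted(inp.survey2.index)
    rows = []
    for n in ns:
        denom = float(inp.survey1.get(n - 5, 1.0))
        ratio = float(inp.survey2[n]) / denom
        rows.append({"n": n, "age_group": f"{n}-{n+4}", "raw_ratio": ratio})
    t = pd.DataFrame(rows)
    if gompertz_slope is None:
        gompertz_slope = estimate_gompertz_slope(t["n"], t["raw_ratio"])
    t["ratio"] = awkward_interval_adjust(
        t["raw_ratio"].to_numpy(), inp.interval_years, gompertz_slope
    )
    conv = apply_coefficients(t, coef)
    out = t.merge(conv[["n", "p5", "q5"]], on="n")
    out.attrs["gompertz_slope"] = gompertz_slope
    q35 = chain_35q15(out["p5"].to_numpy(), expected_groups=None) \
        if len(out) != 7 else chain_35q15(out["p5"].to_numpy())
    return IndirectEstimates(
        by_age=out,
        q35_15=q35,
        method="two_survey",
        reference_period=f"inter-survey interval of {inp.interval_years} years",
    )


def indirect_ci(
    ssh: pd.DataFrame,
    coef: CoefficientTable | None = None,
    sex: str = "f",
    level: float = 0.95,
    method: str = "jackknife",
) -> IndirectEstimates:
    """Recent-deaths estimate with survey-design confidence intervals.

    ``method='jackknife'`` reruns the whole pipeline (tabulate -> convert ->
    chain) on leave-one-cluster-out replicates within strata, the same engine
    as the direct module.  ``method='binomial'`` uses a cluster-free binomial
    approximation on the pooled counts instead.
    """
    coef = coef or CoefficientTable.published_recent()

    def pipeline(df):
        tab = tabulate_summary(df)
        est = recent_method(tab, coef, sex=sex)
        return np.concatenate([est.by_age["q5"].to_numpy(), [est.q35_15]])

    point_est = recent_method(tabulate_summary(ssh), coef, sex=sex)
    point = np.concatenate(
        [point_est.by_age["q5"].to_numpy(), [point_est.q35_15]]
    )
    z = stats.norm.ppf(0.5 + level / 2.0)
    if method == "jackknife":
        se = jackknife_se(ssh, pipeline)
    elif method == "binomial":
        tab = tabulate_summary(ssh).for_sex(sex)
        # delta-method on the ratio, scaled by beta1, plus chaining
        R = tab["reached15"].to_numpy()
        alive5 = (tab["reached15"] - tab["died"] + tab["died_last5"]).to_numpy()
        p_win = tab["ratio"].to_numpy()
        var_ratio = p_win * (1 - p_win) / np.maximum(alive5, 1.0)
        b1 = coef.table.sort_values("n")["beta1"].to_numpy()
        se_q = b1 * np.sqrt(var_ratio)
        p5 = point_est.by_age["p5"].to_numpy()
        prod = np.prod(p5)
        se_chain = prod * np.sqrt(np.sum((se_q / p5) ** 2))
        se = np.concatenate([se_q, [se_chain]])
    else:
        raise ValueError("ci method must be 'jackknife' or 'binomial'")
    lo = np.clip(point - z * se, 0.0, 1.0)
    hi = np.clip(point + z * se, 0.0, 1.0)
    point_est.ci = pd.DataFrame(
        {
            "age_group": list(point_est.by_age["age_group"]) + ["35q15"],
            "estimate": point,
            "se": se,
            "lower": lo,
            "upper": hi,
        }
    )
    point_est.q35_15_ci = (float(lo[-1]), float(hi[-1]))
    return point_est
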