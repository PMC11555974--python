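"""Summary-tabulation of sibling histories and conversion coefficients.

The summary sibling module asks each respondent three questions per sibling
sex: how many siblings reached age 15, how many of those died, and how many
of the deaths happened in the last five years.  From the pooled counts
(R, D, D5) per respondent age group one forms

* ``S(t)   = (R - D) / R``        -- proportion still alive at the survey,
* ``S(t-5) = (R - D + D5) / R``   -- proportion alive five years earlier,
* ``ratio  = S(t) / S(t-5)``      -- survival of the sibling set over the
  five years before the survey.

The recent-deaths method converts the ratio into the life-table survival
probability 5pn with per-age-group linear coefficients,
``5pn = beta0(n) + beta1(n) * ratio``.  This module tabulates the counts,
ships the published coefficient sets, and refits the coefficients from
microsimulated stable populations (one aggregate observation per population
per age group, regressed against the true 5pn of the input life table).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

from sibsurv.schedules import AGE_GROUPS_15_49

__all__ = [
    "SummaryTabulation",
    "CoefficientTable",
    "SimObservation",
    "tabulate_summary",
    "fit_eq4_coefficients",
    "apply_coefficients",
    "age_group_of",
]

_AGE_GROUP_N = {g: int(g.split("-")[0]) for g in AGE_GROUPS_15_49}


def age_group_of(age_months: np.ndarray) -> np.ndarray:
    """5-year age-group labels ('15-19' .. '45-49') from ages in months."""
    age_months = np.asarray(age_months)
    lo = (age_months // 60) * 5
    lab = np.where(
        (age_months >= 180) & (age_months < 600),
        np.char.add(np.char.add(lo.astype(int).astype(str), "-"),
                    (lo + 4).astype(int).astype(str)),
        "",
    )
    return lab


@dataclass(frozen=True)
class SummaryTabulation:
    """Pooled summary-SSH counts per respondent age group and sibling sex.

    ``table`` columns: n, age_group, sib_sex, reached15 (R), died (D),
    died_last5 (D5), s_t, s_tm5, ratio.  Counts are weight-sums, so they need
    not be integers.
    """

    table: pd.DataFrame
    survey_time: float | None = None

    def __post_init__(self):
        t = self.table
        bad = (t["died_last5"] > t["died"] + 1e-9) | (t["died"] > t["reached15"] + 1e-9)
        if bad.any():
            raise ValueError("tabulation violates 0 <= D5 <= D <= R")

    def for_sex(self, sex: str) -> pd.DataFrame:
        """Rows for one sibling sex ('f'/'m'), or pooled with sex='both'."""
        t = self.table
        if sex == "both":
            g = (
                t.groupby(["n", "age_group"], as_index=False)[
                    ["reached15", "died", "died_last5"]
                ].sum()
            )
            return _derive_proportions(g)
        return t[t["sib_sex"] == sex].reset_index(drop=True)

    @classmethod
    def from_proportions(
        cls, age_groups, s_t, s_tm5, sib_sex: str = "f", base: float = 1000.0
    ) -> "SummaryTabulation":
        """Build a tabulation from published proportions instead of raw rows.

        Used for worked examples where only S(t) and S(t-5) are printed; the
        implied pseudo-counts use ``base`` siblings reaching 15 per group.
        """
        s_t = np.asarray(s_t, float)
        s_tm5 = np.asarray(s_tm5, float)
        R = np.full(len(s_t), base)
        D = (1.0 - s_t) * R
        # s_tm5 = (R - D + D5)/R  =>  D5 = R*(s_tm5 - s_t)
        D5 = R * (s_tm5 - s_t)
        df = pd.DataFrame(
            {
                "n": [_AGE_GROUP_N[g] for g in age_groups],
                "age_group": list(age_groups),
                "sib_sex": sib_sex,
                "reached15": R,
                "died": D,
                "died_last5": D5,
            }
        )
        return cls(table=_derive_proportions(df))


def _derive_proportions(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    R, D, D5 = df["reached15"], df["died"], df["died_last5"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["s_t"] = (R - D) / R
        df["s_tm5"] = (R - D + D5) / R
        df["ratio"] = (R - D) / (R - D + D5)
    return df


def tabulate_summary(
    ssh: pd.DataFrame,
    survey_time: float | None = None,
    weights: str | None = "weight",
) -> SummaryTabulation:
    """Tabulate summary counts (R, D, D5) from full sibling-history rows.

    ``ssh`` needs columns ``resp_birth_cmc`` (or ``resp_birth``), ``sib_sex``,
    ``sib_birth_cmc`` (or ``sib_birth``), ``sib_death_cmc`` (or ``sib_death``,
    NaN when alive) and, unless ``survey_time`` is given, ``interview_cmc``
    (or ``interview``).  Boundary conventions: a sibling dying in the month of
    their 15th birthday has reached 15; a death exactly 60 months before the
    survey is inside the window.  Respondents outside 15-49 are excluded (the
    excluded weight is available as ``tab.table.attrs['excluded_weight']``).
    """
    df = ssh.rename(
        columns={
            "resp_birth": "resp_birth_cmc",
            "sib_birth": "sib_birth_cmc",
            "sib_death": "sib_death_cmc",
            "interview": "interview_cmc",
        }
    ).copy()
    t = df["interview_cmc"] if survey_time is None else float(survey_time)
    w = df[weights].to_numpy(float) if weights and weights in df else np.ones(len(df))

    resp_age = np.asarray(t - df["resp_birth_cmc"])
    group = age_group_of(resp_age)
    in_range = group != ""
    excluded = float(w[~in_range].sum())

    birth15 = df["sib_birth_cmc"].to_numpy(float) + 180.0
    death = df["sib_death_cmc"].to_numpy(float)  # NaN when alive
    t_arr = np.broadcast_to(np.asarray(t, float), death.shape)

    reached = (birth15 <= t_arr) & (np.isnan(death) | (death >= birth15))
    died = reached & ~np.isnan(death) & (death < t_arr)
    died5 = died & (death >= t_arr - 60.0)

    tab = pd.DataFrame(
        {
            "age_group": group[in_range],
            "sib_sex": df["sib_sex"].to_numpy()[in_range],
            "reached15": (reached * w)[in_range],
            "died": (died * w)[in_range],
            "died_last5": (died5 * w)[in_range],
        }
    )
    g = tab.groupby(["age_group", "sib_sex"], as_index=False).sum()
    g["n"] = g["age_group"].map(_AGE_GROUP_N)
    g = g[["n", "age_group", "sib_sex", "reached15", "died", "died_last5"]]
    g = g.sort_values(["n", "sib_sex"]).reset_index(drop=True)
    out = _derive_proportions(g)
    out.attrs["excluded_weight"] = excluded
    st = None if survey_time is None else float(survey_time)
    return SummaryTabulation(table=out, survey_time=st)


@dataclass(frozen=True)
class CoefficientTable:
    """Per-age-group linear conversion coefficients beta0(n), beta1(n).

    ``method`` tags the estimator the coefficients belong to
    (``eq4_recent`` or ``eq3_lifetime``).
    """

    table: pd.DataFrame
    method: str

    def __post_init__(self):
        if (self.table["beta1"] <= 0).any():
            raise ValueError("beta1 must be positive")
        if "r_squared" in self.table and (
            (self.table["r_squared"].dropna() < 0).any()
            or (self.table["r_squared"].dropna() > 1).any()
        ):
            raise ValueError("r_squared out of [0, 1]")

    @classmethod
    def published_recent(cls) -> "CoefficientTable":
        """The published recent-deaths (Eq.-4 style) coefficient set."""
        return cls(_packaged("eq4_recent_coefficients.csv"), "eq4_recent")

    @classmethod
    def published_lifetime(cls) -> "CoefficientTable":
        """The published adult lifetime-proportions coefficient set."""
        return cls(_packaged("eq3_lifetime_coefficients.csv"), "eq3_lifetime")

    @classmethod
    def refit_recent(cls) -> "CoefficientTable":
        """Recent-deaths coefficients regenerated by this package's own
        simulation study (see scripts/refit_coefficients.py)."""
        return cls(_packaged("eq4_refit_coefficients.csv"), "eq4_recent_refit")

    def lookup(self, n) -> tuple[float, float]:
        row = self.table[self.table["n"] == int(n)]
        if row.empty:
            raise KeyError(f"no coefficients for age group n={n}")
        return float(row["beta0"].iloc[0]), float(row["beta1"].iloc[0])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "method", self.method)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CoefficientTable":
        df = pd.read_csv(path, comment="#")
        method = str(df.pop("method").iloc[0]) if "method" in df else "custom"
        return cls(df, method)


def _packaged(name: str) -> pd.DataFrame:
    text = resources.files("sibsurv.data").joinpath(name).read_text()
    df = pd.read_csv(_io.StringIO(text), comment="#")
    return df.drop(columns=["method"])


@dataclass(frozen=True)
class SimObservation:
    """One simulated population's aggregate ratios and life-table truths."""

    ratio: pd.Series       # indexed by n = 15..45
    true_5pn: pd.Series    # l(n+5)/l(n) from the input life table
    meta: dict | None = None

    def __post_init__(self):
        p = self.true_5pn
        if ((p <= 0) | (p >= 1)).any():
            raise ValueError("true survival probabilities must be in (0, 1)")


def fit_eq4_coefficients(
    observations: list[SimObservation],
    min_obs: int = 10,
    reliability: pd.Series | None = None,
) -> CoefficientTable:
    """OLS of true 5pn on the summary ratio, one fit per age group.

    ``reliability`` optionally supplies, per age group n, the fraction of the
    ratio's cross-population variance that is signal rather than Monte-Carlo
    noise (estimable from replicate seeds); the slope is divided and the
    intercept recentred accordingly, the textbook measurement-error
    correction.  R-squared and the residual coefficient of variation are
    reported from the uncorrected fit.
    """
    ns = sorted({int(n) for o in observations for n in o.ratio.index})
    rows = []
    for n in ns:
        x = np.array([o.ratio[n] for o in observations if n in o.ratio.index])
        y = np.array([o.true_5pn[n] for o in observations if n in o.true_5pn.index])
        if len(x) < min_obs:
            raise ValueError(f"need at least {min_obs} observations for n={n}")
        if np.ptp(x) < 1e-12:
            raise ValueError(f"ratios are constant for n={n}; design is rank-deficient")
        res = sm.OLS(y, sm.add_constant(x)).fit()
        b0, b1 = float(res.params[0]), float(res.params[1])
        if reliability is not None and n in reliability.index:
            lam = float(reliability[n])
            b1_adj = b1 / lam
            b0 = b0 - (b1_adj - b1) * float(np.mean(x))
            b1 = b1_adj
        resid_cv = float(np.std(res.resid, ddof=2) / np.mean(y))
        rows.append(
            {
                "n": n,
                "age_group": f"{n}-{n+4}",
                "beta0": b0,
                "beta1": b1,
                "r_squared": float(res.rsquared),
                "cv": resid_cv,
            }
        )
    return CoefficientTable(pd.DataFrame(rows), "eq4_recent")


def apply_coefficients(
    tab: SummaryTabulation | pd.DataFrame,
    coef: CoefficientTable,
    sex: str = "f",
) -> pd.DataFrame:
    """Convert tabulated ratios into 5pn = beta0(n) + beta1(n)*ratio.

    Returns a frame with n, age_group, ratio, p5 (clipped to [0,1]) and
    q5 = 1 - p5.  Raises if the coefficient table does not cover every
    tabulated age group.
    """
    rows = tab.for_sex(sex) if isinstance(tab, SummaryTabulation) else tab
    missing = sorted(set(rows["n"]) - set(coef.table["n"]))
    if missing:
        raise KeyError(f"coefficient table lacks age groups n={missing}")
    merged = rows.merge(coef.table[["n", "beta0", "beta1"]], on="n", how="left")
    p5 = (merged["beta0"] + merged["beta1"] * merged["ratio"]).clip(0.0, 1.0)
    return pd.DataFrame(
        {
            "n": merged["n"],
            "age_group": merged["age_group"],
            "ratio": merged["ratio"],
            "p5": p5,
            "q5": 1.0 - p5,
        }
    )
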