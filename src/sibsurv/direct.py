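"""Direct estimation of adult mortality from full sibling histories.

Given one row per reported sibling (with century-month-code dates), the
direct method counts sibling deaths and exposure time by five-year age group
over a reference window before the interview, converts the resulting
age-specific mortality rates into probabilities of dying, and chains the
seven 5qn values for ages 15-49 into the summary index 35q15.  Sampling
variability is assessed with a stratified leave-one-cluster-out jackknife.

Conventions (all month arithmetic on CMC-style integer months):

* age in completed months, ``age = month - birth_cmc``;
* the reference window of ``w`` years covers the 12*w months ending the
  month *before* the interview month (``include_interview_month=True``
  shifts it to end at the interview month);
* a sibling contributes exposure from the later of the window start and
  their 15th-birthday month; the month of death contributes half a month of
  exposure, earlier alive months a full month;
* deaths are assigned to the age group containing the age at death.

The canonical dataset is a pandas DataFrame with columns ``resp_id``,
``cluster``, ``stratum``, ``weight``, ``interview_cmc``, ``sib_sex``,
``sib_alive``, ``sib_birth_cmc``, ``sib_death_cmc`` (NaN when alive) and
optionally ``resp_birth_cmc``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from sibsurv.schedules import AGE_GROUPS_15_49, chain_35q15, rate_to_probability

__all__ = [
    "validate_ssh",
    "deaths_and_exposure",
    "direct_estimates",
    "estimates_from_counts",
    "jackknife_ci",
    "DirectEstimates",
]

_AGE_LO_MONTHS = np.arange(180, 600, 60)  # 15-19 .. 45-49


def validate_ssh(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a full-SSH table into valid rows and a rejects report.

    Rejected (with a reason column): death before birth, interview before
    birth, non-positive weight, missing survival status, dead siblings with
    no death date.  Rejects are returned, never silently dropped.
    """
    required = [
        "resp_id", "weight", "interview_cmc", "sib_sex", "sib_alive",
        "sib_birth_cmc", "sib_death_cmc",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    df = df.copy()
    death = df["sib_death_cmc"]
    alive = df["sib_alive"].astype("boolean")
    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[alive.isna()] = "missing survival status"
    reasons[(~alive.fillna(True)) & death.isna()] = "dead sibling without death date"
    reasons[death.notna() & (death < df["sib_birth_cmc"])] = "death before birth"
    reasons[df["interview_cmc"] < df["sib_birth_cmc"]] = "born after interview"
    reasons[df["weight"] <= 0] = "non-positive weight"
    bad = reasons != ""
    rejects = df[bad].assign(reject_reason=reasons[bad])
    return df[~bad].reset_index(drop=True), rejects.reset_index(drop=True)


def deaths_and_exposure(
    data: pd.DataFrame,
    window_years: int = 5,
    sex: str = "both",
    include_interview_month: bool = False,
    death_month_exposure: float = 0.5,
) -> pd.DataFrame:
    """Weighted deaths and person-years per 5-year age group 15-49.

    Returns a frame with n, age_group, deaths, person_years.  Rows with
    missing survival status are excluded (see :func:`validate_ssh` for the
    accounting); ``sex`` restricts to sibling sex 'f' or 'm'.
    """
    df, _ = validate_ssh(data)
    if sex != "both":
        df = df[df["sib_sex"] == sex]
    v = df["interview_cmc"].to_numpy(float)
    end = v if include_interview_month else v - 1.0  # last month in window
    w_len = 12.0 * window_years
    start = end - w_len + 1.0
    b = df["sib_birth_cmc"].to_numpy(float)
    death = df["sib_death_cmc"].to_numpy(float)
    wgt = df["weight"].to_numpy(float)
    has_death = ~np.isnan(death)

    rows = []
    for lo_m in _AGE_LO_MONTHS:
        cell_first = b + lo_m            # month of the lower exact age
        cell_last = b + lo_m + 59.0      # last month inside the group
        first = np.maximum(cell_first, start)
        last_alive = np.where(has_death, death - 1.0, end)
        last = np.minimum.reduce([cell_last, end, last_alive])
        full_months = np.clip(last - first + 1.0, 0.0, None)
        died_in_cell = (
            has_death
            & (death >= first)
            & (death <= np.minimum(cell_last, end))
            & (death >= cell_first)
        )
        months = full_months + death_month_exposure * died_in_cell
        lo = int(lo_m // 12)
        rows.append(
            {
                "n": lo,
                "age_group": f"{lo}-{lo+4}",
                "deaths": float((died_in_cell * wgt).sum()),
                "person_years": float((months * wgt).sum() / 12.0),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DirectEstimates:
    """Age-specific rates/probabilities and the chained 35q15."""

    by_age: pd.DataFrame           # n, age_group, deaths, person_years, nmx, q5, p5
    q35_15: float
    window_years: int
    sex: str
    ci: pd.DataFrame | None = field(default=None)   # optional jackknife CIs
    q35_15_ci: tuple[float, float] | None = None

    def __post_init__(self):
        chained = chain_35q15(self.by_age["p5"].to_numpy())
        if abs(chained - self.q35_15) > 1e-10:
            raise AssertionError("chained 35q15 inconsistent with age-specific p5")


def estimates_from_counts(
    counts: pd.DataFrame, window_years: int = 5, sex: str = "both"
) -> DirectEstimates:
    """Rates -> probabilities -> chained 35q15 from a deaths/exposure table.

    ``counts`` needs columns n, age_group, deaths, person_years for the seven
    groups 15-49.  Cells without exposure make the chain undefined and raise.
    """
    t = counts.sort_values("n").reset_index(drop=True)
    if list(t["age_group"]) != AGE_GROUPS_15_49:
        raise ValueError(f"expected age groups {AGE_GROUPS_15_49}")
    if (t["person_years"] <= 0).any():
        empty = t.loc[t["person_years"] <= 0, "age_group"].tolist()
        raise ValueError(
            f"no exposure in age groups {empty}; cannot chain 35q15"
        )
    t["nmx"] = t["deaths"] / t["person_years"]
    t["q5"] = rate_to_probability(t["nmx"].to_numpy(), n=5)
    t["p5"] = 1.0 - t["q5"]
    return DirectEstimates(
        by_age=t,
        q35_15=chain_35q15(t["p5"].to_numpy()),
        window_years=window_years,
        sex=sex,
    )


def direct_estimates(
    data: pd.DataFrame,
    window_years: int = 5,
    sex: str = "both",
    ci: str | None = None,
    level: float = 0.95,
    **exposure_kwargs,
) -> DirectEstimates:
    """Full direct pipeline: exposure, rates, probabilities, chained 35q15.

    ``ci='jackknife'`` adds stratified-jackknife confidence bounds for the
    seven 5qn and for 35q15.
    """
    counts = deaths_and_exposure(data, window_years, sex=sex, **exposure_kwargs)
    est = estimates_from_counts(counts, window_years, sex)
    if ci == "jackknife":
        def estimator(d):
            c = deaths_and_exposure(d, window_years, sex=sex, **exposure_kwargs)
            e = estimates_from_counts(c, window_years, sex)
            return np.concatenate([e.by_age["q5"].to_numpy(), [e.q35_15]])

        point = np.concatenate([est.by_age["q5"].to_numpy(), [est.q35_15]])
        se = jackknife_se(data, estimator)
        z = stats.norm.ppf(0.5 + level / 2.0)
        lo = np.clip(point - z * se, 0.0, 1.0)
        hi = np.clip(point + z * se, 0.0, 1.0)
        est.ci = pd.DataFrame(
            {
                "age_group": list(est.by_age["age_group"]) + ["35q15"],
                "estimate": point,
                "se": se,
                "lower": lo,
                "upper": hi,
            }
        )
        est.q35_15_ci = (float(lo[-1]), float(hi[-1]))
    return est


def _collapse_single_clusters(df: pd.DataFrame) -> pd.DataFrame:
    """Merge single-cluster strata into an adjacent stratum (logged in attrs)."""
    counts = df.groupby("stratum")["cluster"].nunique()
    singles = counts[counts < 2].index.tolist()
    if not singles:
        return df
    df = df.copy()
    strata = sorted(counts.index)
    mapping = {}
    for s in singles:
        others = [x for x in strata if x not in singles]
        if not others:
            raise ValueError("all strata have a single cluster; jackknife impossible")
        target = min(others, key=lambda x: abs(strata.index(x) - strata.index(s)))
        mapping[s] = target
    df["stratum"] = df["stratum"].replace(mapping)
    df.attrs["collapsed_strata"] = mapping
    return df


def jackknife_se(data: pd.DataFrame, estimator) -> np.ndarray:
    """Stratified leave-one-cluster-out jackknife standard errors.

    ``estimator`` maps a dataset to a vector of estimates.  Within each
    stratum h with n_h clusters, variance is
    (n_h - 1)/n_h * sum_i (theta_(hi) - mean_h)^2, summed over strata.
    Single-cluster strata are collapsed into the nearest neighbour first.
    """
    df = _collapse_single_clusters(data)
    var = None
    for h, sub_idx in df.groupby("stratum").groups.items():
        stratum_mask = df["stratum"] == h
        clusters = df.loc[stratum_mask, "cluster"].unique()
        n_h = len(clusters)
        reps = []
        for c in clusters:
            keep = ~(stratum_mask & (df["cluster"] == c))
            reps.append(estimator(df[keep]))
        reps = np.asarray(reps, dtype=float)
        mean_h = reps.mean(axis=0)
        contrib = (n_h - 1) / n_h * ((reps - mean_h) ** 2).sum(axis=0)
        var = contrib if var is None else var + contrib
    return np.sqrt(var)


def jackknife_ci(
    data: pd.DataFrame, estimator, level: float = 0.95
) -> pd.DataFrame:
    """Normal-approximation CIs from :func:`jackknife_se`, clipped to [0, 1]."""
    point = np.asarray(estimator(data), dtype=float)
    se = jackknife_se(data, estimator)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return pd.DataFrame(
        {
            "estimate": point,
            "se": se,
            "lower": np.clip(point - z * se, 0.0, 1.0),
            "upper": np.clip(point + z * se, 0.0, 1.0),
        }
    )
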