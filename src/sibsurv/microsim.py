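"""Closed-population stable microsimulation with kinship tracking.

The simulator emulates a SOCSIM-style monthly-clock model: a founding
population drawn from the stable age distribution implied by the input
schedules, deaths governed by the relational-logit life table, and births
governed by the relational-Gompertz fertility schedule applied to all women
aged 15-49 irrespective of parity, subject only to a minimum birth interval.
Every individual born during the run has an identified mother, so full
sibling histories can be reconstructed exactly by grouping children on the
mother's id.

Time is measured in months from the start of the run.  An individual with
``birth=b`` and ``death=d`` lives through months ``b .. d-1`` and dies during
month ``d``; ``d - b`` is the age in completed months.  The survey at the end
of a run happens at time ``end_time``: a person is alive at the survey iff
``death >= end_time``.

Death ages are drawn once, at birth, by inverse-CDF sampling of the monthly
survival curve, which is distributionally identical to month-by-month hazard
draws for an age-only hazard and reproduces the input life table exactly.
Births remain month-by-month Bernoulli events because the minimum-interval
rule makes them state-dependent.  The birth hazard applied to interval-
eligible women is inflated by lambda = mu/(1 - mu*d) (mu = monthly schedule
rate, d = minimum interval) so that the *population* age-specific fertility
rates match the schedule despite post-birth blocking, and the schedule itself
is pre-scaled so its Lotka growth rate equals the configured ``r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from sibsurv.schedules import (
    FertilitySchedule,
    LifeTable,
    brass_logit_lifetable,
    fertility_scale_for_growth,
    relational_gompertz_fertility,
    stable_age_structure,
)

__all__ = [
    "SimConfig",
    "Population",
    "SiblingHistories",
    "run_simulation",
    "period_rates",
    "extract_ssh",
    "PopulationExtinct",
]

FEMALE, MALE = 0, 1
RESP_AGE_MIN_MONTHS, RESP_AGE_MAX_MONTHS = 180, 600  # respondents aged 15-49


class PopulationExtinct(RuntimeError):
    """Raised when the simulated population dies out before the horizon."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one stable-population run.

    The four relational parameters and ``r`` define the demographic regime;
    ``target_final_size`` fixes the expected number of survivors at the end of
    the run (the founding size is back-projected as N0 = target*exp(-r*T)).
    """

    alpha_m: float = -0.6
    beta_m: float = 1.1
    alpha_f: float = 0.1
    beta_f: float = 1.4
    r: float = 0.01
    horizon_years: int = 150
    target_final_size: int = 40_000
    min_birth_interval_months: int = 10
    sex_ratio_at_birth: float = 0.512  # probability a birth is male
    seed: int = 0

    def __post_init__(self):
        if self.horizon_years < 100:
            raise ValueError("horizon must be at least 100 years")
        if self.target_final_size < 1_000:
            raise ValueError("target final size must be at least 1,000")
        if self.min_birth_interval_months < 9:
            raise ValueError("minimum birth interval must be at least 9 months")

    def life_table(self) -> LifeTable:
        return brass_logit_lifetable(self.alpha_m, self.beta_m)

    def fertility(self) -> FertilitySchedule:
        """The input fertility schedule, Lotka-scaled to the target growth rate."""
        base = relational_gompertz_fertility(self.alpha_f, self.beta_f)
        scale = fertility_scale_for_growth(
            self.life_table(), base, self.r, 1.0 - self.sex_ratio_at_birth
        )
        return FertilitySchedule(rates=base.rates * scale, name=base.name + "-scaled")


@dataclass
class Population:
    """Event log of a completed run: one row per individual ever alive."""

    config: SimConfig | None
    sex: np.ndarray        # int8, 0 female / 1 male
    birth: np.ndarray      # int32 months (negative for founders)
    death: np.ndarray      # int32 month of death
    mother: np.ndarray     # int32 index into arrays, -1 for founders
    end_time: int          # months simulated
    alive_series: np.ndarray | None = field(repr=False, default=None)

    @property
    def n_ever(self) -> int:
        return len(self.birth)

    def alive_at(self, t: int) -> np.ndarray:
        return (self.birth < t) & (self.death >= t)

    @property
    def final_size(self) -> int:
        return int(self.alive_at(self.end_time).sum())

    def realized_growth_rate(self, last_years: int = 50) -> float:
        """Log-linear fit of the yearly alive counts over the final window."""
        years = np.arange(self.end_time // 12)
        counts = self.alive_series[years * 12]
        sel = years >= years[-1] - last_years + 1
        coef = np.polyfit(years[sel], np.log(counts[sel]), 1)
        return float(coef[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n_ever),
                "sex": np.where(self.sex == FEMALE, "f", "m"),
                "birth": self.birth,
                "death": self.death,
                "mother_id": self.mother,
                "end_time": self.end_time,
            }
        )

    def to_event_log(self, path) -> None:
        """Tabular text export (one row per individual); also the fixture format."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_event_log(cls, path, config: SimConfig | None = None) -> "Population":
        df = pd.read_csv(path)
        return cls(
            config=config,
            sex=np.where(df["sex"].to_numpy() == "f", FEMALE, MALE).astype(np.int8),
            birth=df["birth"].to_numpy(np.int32),
            death=df["death"].to_numpy(np.int32),
            mother=df["mother_id"].to_numpy(np.int32),
            end_time=int(df["end_time"].iloc[0]),
        )


def monthly_survival_curve(lt: LifeTable) -> np.ndarray:
    """S[m] = probability of being alive after m completed months of life.

    Geometric interpolation of l(x) within each year of age, so annual
    survivorship is reproduced exactly.
    """
    omega = lt.omega
    lx = lt.lx[: omega + 2].copy()
    months = np.arange((omega + 1) * 12 + 1)
    y = months // 12
    k = months % 12
    l0 = lx[np.minimum(y, omega + 1)]
    l1 = lx[np.minimum(y + 1, omega + 1)]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(l0 > 0, np.where(l1 > 0, l1 / l0, 1e-14), 0.0)
        s = l0 * ratio ** (k / 12.0)
    s[-1] = 0.0
    return s


@njit(cache=True)
def _sample_death(S, u):
    """Months of life completed: largest m with S[m] > u (S is decreasing)."""
    lo, hi = 0, len(S) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if S[mid] <= u:
            hi = mid
        else:
            lo = mid + 1
    return lo - 1


@njit(cache=True)
def _engine(horizon, S2, row_of_b, b_off, p_birth, frac_female, d_int,
            founder_ages, cap, seed):
    """Monthly event loop.

    ``S2`` holds one monthly survival curve per birth-cohort row;
    ``row_of_b[b + b_off]`` maps a birth month to its row (a single shared
    row when mortality is constant over time).
    """
    np.random.seed(seed)
    n_f = len(founder_ages)
    sex = np.empty(cap, dtype=np.int8)
    birth = np.empty(cap, dtype=np.int32)
    death = np.empty(cap, dtype=np.int32)
    mother = np.empty(cap, dtype=np.int32)
    last_birth = np.empty(cap, dtype=np.int32)
    deaths_sched = np.zeros(horizon + 2, dtype=np.int64)
    alive_series = np.zeros(horizon, dtype=np.int64)

    n = 0
    alive = 0
    for i in range(n_f):
        a = founder_ages[i]
        sex[n] = 0 if np.random.random() < frac_female else 1
        birth[n] = -a
        S = S2[row_of_b[-a + b_off]]
        u = np.random.random() * S[a]
        death[n] = -a + _sample_death(S, u)
        mother[n] = -1
        last_birth[n] = -10_000
        d = death[n]
        if d >= 1:
            alive += 1
            if d < horizon:
                deaths_sched[d] += 1
        n += 1

    max_lived = S2.shape[1] - 2
    for t in range(horizon):
        n0 = n
        births_this = 0
        for i in range(n0):
            if sex[i] != 0:
                continue
            if death[i] <= t or birth[i] > t:
                continue
            age = t - birth[i]
            if age < RESP_AGE_MIN_MONTHS or age >= RESP_AGE_MAX_MONTHS:
                continue
            if t - last_birth[i] < d_int:
                continue
            if np.random.random() < p_birth[age - RESP_AGE_MIN_MONTHS]:
                if n >= cap:
                    return (sex[:0], birth[:0], death[:0], mother[:0],
                            alive_series, -2)
                sex[n] = 0 if np.random.random() < frac_female else 1
                birth[n] = t
                lived = _sample_death(S2[row_of_b[t + b_off]], np.random.random())
                if lived > max_lived:
                    lived = max_lived
                death[n] = t + lived
                mother[n] = i
                last_birth[n] = -10_000
                last_birth[i] = t
                d = death[n]
                if d > t:
                    births_this += 1
                    if d < horizon:
                        deaths_sched[d] += 1
                n += 1
        alive += births_this - deaths_sched[t]
        alive_series[t] = alive
        if alive <= 0:
            return sex[:n], birth[:n], death[:n], mother[:n], alive_series, t
    return sex[:n], birth[:n], death[:n], mother[:n], alive_series, -9


def cohort_survival_curves(
    tables: list[LifeTable], horizon_months: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Cohort monthly survival curves under year-by-year period mortality.

    ``tables[y]`` is the period life table in force during simulation year y
    (years before the start reuse ``tables[0]``, after the end ``tables[-1]``).
    Returns (S2, row_of_b, b_off) for the event engine: one row per birth
    month from -(omega*12) to horizon_months-1.
    """
    n_years = len(tables)
    omega = min(t.omega for t in tables)
    n_m = (omega + 1) * 12
    # monthly death probability by (age month, period year)
    q = np.empty((n_m, n_years))
    for y, lt in enumerate(tables):
        lx = lt.lx
        ages = np.arange(n_m) // 12
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(lx[ages] > 0, lx[ages + 1] / np.maximum(lx[ages], 1e-300), 0.0)
        q[:, y] = 1.0 - ratio ** (1.0 / 12.0)
    b_off = n_m
    births = np.arange(-n_m, horizon_months)
    S2 = np.empty((len(births), n_m + 1))
    age_idx = np.arange(n_m)
    for i, b in enumerate(births):
        yrs = np.clip((b + age_idx) // 12, 0, n_years - 1)
        p = 1.0 - q[age_idx, yrs]
        S2[i, 0] = 1.0
        np.cumprod(p, out=S2[i, 1:])
    S2[:, -1] = 0.0
    row_of_b = np.arange(len(births), dtype=np.int64)
    return S2, row_of_b, b_off


def run_simulation(config: SimConfig, alpha_m_path=None) -> Population:
    """Run one microsimulation.

    With the default constant schedules this is a stable-population run.
    ``alpha_m_path`` optionally supplies the mortality level parameter
    alpha_m for each simulation year (length ``horizon_years``), letting
    mortality drift over time while fertility stays fixed; the founding age
    structure and fertility calibration then use the year-0 life table.

    Raises :class:`PopulationExtinct` if the population dies out before the
    horizon, with the month of extinction in the message.
    """
    horizon = config.horizon_years * 12
    if alpha_m_path is not None:
        if len(alpha_m_path) != config.horizon_years:
            raise ValueError("alpha_m_path must have one value per simulation year")
        tables = [brass_logit_lifetable(a, config.beta_m) for a in alpha_m_path]
        lt = tables[0]
        S2, row_of_b, b_off = cohort_survival_curves(tables, horizon)
    else:
        lt = config.life_table()
        S = monthly_survival_curve(lt)
        S2 = S[None, :]
        row_of_b = np.zeros(horizon + len(S), dtype=np.int64)
        b_off = len(S) - 1
    fert = config.fertility()

    # population-level monthly rate -> hazard among interval-eligible women;
    # the blocked fraction at each month of age is the chance of a birth in
    # the preceding d months, so rising schedules are not over-inflated
    mu_year = fert.rates / 12.0
    mu = np.repeat(mu_year, 12)  # month of age 180..599
    d_int = config.min_birth_interval_months
    mu_pad = np.concatenate([np.zeros(d_int), mu])
    blocked = np.array(
        [mu_pad[i : i + d_int].sum() for i in range(len(mu))]
    )
    if np.any(blocked >= 0.95):
        raise ValueError("fertility too high for the minimum birth interval")
    lam = mu / (1.0 - blocked)
    p_birth = 1.0 - np.exp(-lam)

    n0 = max(
        int(round(config.target_final_size * np.exp(-config.r * config.horizon_years))),
        30,
    )
    stable_age_structure(lt, fert, config.r)  # validates r
    rng = np.random.default_rng(config.seed)
    # monthly stable structure c(m) ∝ exp(-r m/12) S0[m], from the year-0 table
    S0 = monthly_survival_curve(lt)
    m = np.arange(min(len(S0) - 1, S2.shape[1] - 1))
    c = np.exp(-config.r * m / 12.0) * S0[m]
    c = c / c.sum()
    founder_ages = rng.choice(len(c), size=n0, p=c).astype(np.int64)

    cap = int(config.target_final_size * 6 + 120 * config.horizon_years)
    sex, birth, death, mother, alive_series, status = _engine(
        horizon, S2, row_of_b, b_off, p_birth, 1.0 - config.sex_ratio_at_birth,
        config.min_birth_interval_months, founder_ages, cap,
        int(rng.integers(0, 2**31 - 1)),
    )
    if status == -2:
        raise MemoryError("simulation exceeded its preallocated capacity")
    if status >= 0:
        raise PopulationExtinct(
            f"population extinct at month {status} "
            f"(r={config.r}, alpha_m={config.alpha_m}, seed={config.seed}); "
            "increase target_final_size or reseed"
        )
    return Population(
        config=config, sex=sex, birth=birth, death=death, mother=mother,
        end_time=horizon, alive_series=alive_series,
    )


def period_rates(
    pop: Population, window_years: int = 5, age_max: int = 85
) -> pd.DataFrame:
    """Deaths and person-years by 5-year age group and sex for the final window.

    Months lived in each (age group x window) cell are summed exactly, with a
    half month credited for the month of death.  Cells with no exposure are
    reported with NaN rates rather than zero.
    """
    if window_years * 12 > pop.end_time:
        raise ValueError("window longer than the simulated horizon")
    t1 = pop.end_time  # exclusive
    t0 = t1 - window_years * 12
    rows = []
    b, d, sx = pop.birth, pop.death, pop.sex
    for lo in range(0, age_max, 5):
        lo_m, hi_m = lo * 12, (lo + 5) * 12
        for s, slab in ((FEMALE, "f"), (MALE, "m")):
            sel = sx == s
            start = np.maximum(b[sel] + lo_m, t0)
            stop = np.minimum(np.minimum(b[sel] + hi_m, d[sel]), t1)
            months = np.clip(stop - start, 0, None).astype(float)
            dies_in = (
                (d[sel] >= t0) & (d[sel] < t1)
                & (d[sel] - b[sel] >= lo_m) & (d[sel] - b[sel] < hi_m)
            )
            months += 0.5 * dies_in  # half-month credit in the death month
            py = months.sum() / 12.0
            deaths = int(dies_in.sum())
            rows.append(
                {
                    "age_group": f"{lo}-{lo+4}",
                    "sex": slab,
                    "deaths": deaths,
                    "person_years": py,
                    "nmx": deaths / py if py > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SiblingHistories:
    """Reconstructed full sibling histories at a survey time.

    ``respondents`` has one row per respondent (everyone alive and aged 15-49
    at the survey who was born during the run); ``pairs`` has one row per
    (respondent, maternal sibling), excluding the respondent from their own
    sibling list.  Respondents without siblings appear in ``respondents`` but
    contribute no rows to ``pairs``.
    """

    respondents: pd.DataFrame
    pairs: pd.DataFrame
    survey_time: int

    def to_full_ssh(self, rng=None, n_clusters: int = 0) -> pd.DataFrame:
        """Canonical full-SSH dataset for the direct-estimation module.

        Optionally assigns respondents at random to ``n_clusters`` sampling
        clusters (single stratum) so the jackknife machinery can be exercised.
        """
        df = pd.DataFrame(
            {
                "resp_id": self.pairs["resp_id"],
                "resp_birth_cmc": self.pairs["resp_birth"],
                "cluster": 0,
                "stratum": 0,
                "weight": 1.0,
                "interview_cmc": self.survey_time,
                "sib_sex": self.pairs["sib_sex"],
                "sib_alive": self.pairs["sib_death"].isna(),
                "sib_birth_cmc": self.pairs["sib_birth"],
                "sib_death_cmc": self.pairs["sib_death"],
            }
        )
        if n_clusters > 0:
            rng = rng if rng is not None else np.random.default_rng(0)
            ids = self.respondents["resp_id"].to_numpy()
            cl = pd.Series(rng.integers(0, n_clusters, size=len(ids)), index=ids)
            df["cluster"] = cl.reindex(df["resp_id"]).to_numpy()
        return df


def extract_ssh(pop: Population, at_time: int | None = None) -> SiblingHistories:
    """Reconstruct sibling survival histories as of ``at_time``.

    Respondents are all persons alive and aged 15-49 at ``at_time`` who were
    born during the simulation (founders have no recorded mother; with a
    150-year horizon none are of respondent age anyway).  Siblings are all
    other children of the respondent's mother, alive or dead; deaths after
    ``at_time`` are censored to "alive at survey".
    """
    t = pop.end_time if at_time is None else int(at_time)
    if t > pop.end_time:
        raise ValueError("at_time beyond the end of the simulation")
    b, d, sx, mo = pop.birth, pop.death, pop.sex, pop.mother
    age = t - b
    is_resp = (
        (mo >= 0)
        & (d >= t)
        & (age >= RESP_AGE_MIN_MONTHS)
        & (age < RESP_AGE_MAX_MONTHS)
    )
    resp_idx = np.flatnonzero(is_resp)
    respondents = pd.DataFrame(
        {
            "resp_id": resp_idx,
            "resp_birth": b[resp_idx],
            "resp_sex": np.where(sx[resp_idx] == FEMALE, "f", "m"),
            "resp_age_months": age[resp_idx],
            "mother_id": mo[resp_idx],
        }
    )
    born = np.flatnonzero(mo >= 0)
    kids = pd.DataFrame(
        {
            "sib_id": born,
            "mother_id": mo[born],
            "sib_sex": np.where(sx[born] == FEMALE, "f", "m"),
            "sib_birth": b[born],
            "sib_death_raw": d[born],
        }
    )
    pairs = respondents.merge(kids, on="mother_id", how="inner")
    pairs = pairs[pairs["sib_id"] != pairs["resp_id"]].reset_index(drop=True)
    dead = pairs["sib_death_raw"] < t
    pairs["sib_death"] = np.where(dead, pairs["sib_death_raw"], np.nan)
    pairs = pairs.drop(columns="sib_death_raw")
    pairs["interview"] = t
    return SiblingHistories(respondents=respondents, pairs=pairs, survey_time=t)
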