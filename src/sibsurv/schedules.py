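"""Relational demographic models and life-table arithmetic.

This module provides the building blocks shared by the estimators and the
microsimulation:

* :class:`MortalityStandard` and :func:`brass_logit_lifetable` implement the
  two-parameter relational logit life-table system.  A standard survivorship
  curve ``ls(x)`` is expressed as half-log-odds ``Ys(x) = 0.5*ln((1-ls)/ls)``;
  new life tables are generated as ``Y(x) = alpha + beta*Ys(x)``.  With this
  sign convention larger ``alpha`` means *higher* mortality.
* :class:`FertilitySchedule` and :func:`relational_gompertz_fertility`
  implement the relational Gompertz fertility model, which applies the same
  (alpha, beta) idea to the double-log (gompit) transform of the proportion of
  total fertility achieved by each age.
* :func:`stable_age_structure` builds the stable-population age distribution
  ``c(x) ∝ exp(-r*x) * l(x)`` used to seed the microsimulation.
* :func:`rate_to_probability` and :func:`chain_q` convert age-specific
  mortality rates into probabilities of dying and chain them into summary
  indices such as 35q15.
* :func:`west_model_lookup` converts a single survivorship ratio into 35q15
  through a one-parameter model life-table family (a synthetic, logit-generated
  stand-in for the Princeton West family; see :func:`synthetic_west_family`).
"""

from __future__ import annotations

import functools
import io
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "MortalityStandard",
    "LifeTable",
    "FertilitySchedule",
    "StablePopulation",
    "brass_logit_lifetable",
    "relational_gompertz_fertility",
    "stable_age_structure",
    "rate_to_probability",
    "chain_q",
    "chain_35q15",
    "west_model_lookup",
    "synthetic_west_family",
    "lotka_growth_rate",
    "fertility_scale_for_growth",
]

OMEGA = 110  # open-interval age for generated life tables

AGE_GROUPS_15_49 = ["15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49"]


def _load_packaged_csv(name: str) -> pd.DataFrame:
    text = resources.files("sibsurv.data").joinpath(name).read_text()
    return pd.read_csv(io.StringIO(text), comment="#")


def survival_to_logit(lx: np.ndarray) -> np.ndarray:
    """Half-log-odds of the probability of having died: 0.5*ln((1-l)/l)."""
    lx = np.asarray(lx, dtype=float)
    if np.any((lx <= 0.0) | (lx >= 1.0)):
        raise ValueError("logits are only defined for survivorship in (0, 1)")
    return 0.5 * np.log((1.0 - lx) / lx)


def logit_to_survival(y: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(2.0 * np.asarray(y, dtype=float)))


@dataclass(frozen=True)
class MortalityStandard:
    """A standard survivorship curve expressed in logits at single-year ages.

    ``ages`` runs from 1 to the open-interval age; age 0 (where the logit is
    infinite because l0 = 1) is implicit.
    """

    name: str
    ages: np.ndarray
    logits: np.ndarray

    def __post_init__(self):
        if len(self.ages) != len(self.logits):
            raise ValueError("ages and logits must align")
        if not np.all(np.isfinite(self.logits)):
            raise ValueError("standard has non-finite logits in its interior")
        if np.any(np.diff(self.logits) <= 0):
            raise ValueError("standard logits must increase strictly with age")

    @classmethod
    def brass_general(cls) -> "MortalityStandard":
        """The Brass general standard, interpolated to single years of age.

        The packaged knots (ages 1-4 yearly, then quinquennial to 85) are
        interpolated linearly on the logit scale -- the conventional way the
        standard is used -- and extended beyond age 85 by letting the
        five-year logit increments keep growing at their last observed ratio,
        which closes survivorship smoothly by age 110.
        """
        return _brass_general_cached()


@functools.lru_cache(maxsize=1)
def _brass_general_cached() -> MortalityStandard:
    tab = _load_packaged_csv("brass_general_standard.csv")
    knots = tab[tab["age"] > 0]
    ages = knots["age"].to_numpy(float)
    ys = survival_to_logit(knots["lx"].to_numpy())
    # extend in 5-year steps beyond the last knot: increments grow geometrically
    inc = ys[-1] - ys[-2]
    ratio = (ys[-1] - ys[-2]) / (ys[-2] - ys[-3])
    ext_ages, ext_ys = [], []
    a, y = ages[-1], ys[-1]
    while a < OMEGA:
        inc *= ratio
        a += 5.0
        y += inc
        ext_ages.append(a)
        ext_ys.append(y)
    ages = np.concatenate([ages, ext_ages])
    ys = np.concatenate([ys, ext_ys])
    single = np.arange(1, OMEGA + 1, dtype=float)
    ys_single = np.interp(single, ages, ys)
    return MortalityStandard("brass-general", single, ys_single)


@dataclass(frozen=True)
class LifeTable:
    """A complete single-year life table with radix l(0) = 1.

    ``lx`` holds survivorship at exact ages ``0..omega+1`` with
    ``lx[omega+1] = 0`` closing the table.
    """

    sex: str
    ages: np.ndarray
    lx: np.ndarray

    def __post_init__(self):
        lx = self.lx
        if lx[0] != 1.0:
            raise ValueError("life table radix must be 1")
        if np.any(np.diff(lx) > 1e-12):
            raise ValueError("survivorship must be non-increasing")
        if np.any((lx < 0) | (lx > 1)):
            raise ValueError("survivorship out of [0, 1]")

    @property
    def omega(self) -> int:
        return int(self.ages[-1]) - 1

    def survival(self, age: float) -> float:
        """l(x) at an exact (possibly fractional) age, geometric within years."""
        x = float(age)
        if x <= 0:
            return 1.0
        i = min(int(x), self.omega)
        l0, l1 = self.lx[i], self.lx[i + 1]
        if l0 <= 0:
            return 0.0
        frac = x - i
        if l1 <= 0:
            return float(l0 * (1e-12 / l0) ** frac) if frac > 0 else float(l0)
        return float(l0 * (l1 / l0) ** frac)

    @property
    def qx(self) -> np.ndarray:
        """Single-year probabilities of dying, age 0..omega."""
        lx = self.lx
        with np.errstate(divide="ignore", invalid="ignore"):
            q = 1.0 - lx[1:] / lx[:-1]
        return np.where(lx[:-1] > 0, q, 1.0)

    @property
    def e0(self) -> float:
        """Life expectancy at birth, trapezoidal person-years."""
        return float(np.trapezoid(self.lx, self.ages))

    def npx(self, x: int, n: int) -> float:
        if self.lx[x] <= 0:
            return 0.0
        return float(self.lx[x + n] / self.lx[x])

    def nqx(self, x: int, n: int) -> float:
        return 1.0 - self.npx(x, n)

    @property
    def q35_15(self) -> float:
        """35q15: probability a 15-year-old dies before exact age 50."""
        return self.nqx(15, 35)

    def five_pn(self, n: int) -> float:
        """5pn = l(n+5)/l(n), survival across a conventional 5-year group."""
        return self.npx(n, 5)

    def nmx(self, x: int, n: int) -> float:
        """Central death rate over [x, x+n), trapezoidal person-years."""
        lx = self.lx[x : x + n + 1]
        py = np.trapezoid(lx, dx=1.0)
        if py <= 0:
            return float("nan")
        return float((lx[0] - lx[-1]) / py)


def brass_logit_lifetable(
    alpha_m: float, beta_m: float, standard: MortalityStandard | None = None,
    sex: str = "both",
) -> LifeTable:
    """Generate a life table from the relational logit model.

    Y(x) = alpha_m + beta_m * Ys(x), l(x) = 1 / (1 + exp(2 Y(x))).
    (alpha_m, beta_m) = (0, 1) reproduces the standard exactly; larger alpha_m
    gives uniformly lower survivorship.
    """
    if beta_m <= 0:
        raise ValueError("beta_m must be positive")
    std = standard or MortalityStandard.brass_general()
    y = alpha_m + beta_m * std.logits
    lx = np.concatenate([[1.0], logit_to_survival(y), [0.0]])
    ages = np.arange(len(lx), dtype=float)
    return LifeTable(sex=sex, ages=ages, lx=lx)


@dataclass(frozen=True)
class FertilitySchedule:
    """Single-year age-specific fertility rates over [15, 50).

    ``rates[i]`` is the rate for age interval [15+i, 16+i).
    """

    rates: np.ndarray
    name: str = "fertility"

    ALPHA_AGE: int = field(default=15, init=False)
    BETA_AGE: int = field(default=50, init=False)

    def __post_init__(self):
        if len(self.rates) != 35:
            raise ValueError("expected 35 single-year rates for ages 15..49")
        if np.any(self.rates < 0):
            raise ValueError("fertility rates must be non-negative")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(15, 50)

    @property
    def tfr(self) -> float:
        return float(self.rates.sum())

    @property
    def mean_age(self) -> float:
        """Mean age of the schedule (mid-interval convention), in years."""
        mids = self.ages + 0.5
        return float(np.sum(mids * self.rates) / self.tfr)

    def gompits(self) -> tuple[np.ndarray, np.ndarray]:
        """Gompits -ln(-ln F(x)/TF) of cumulated fertility at ages 16..49."""
        cum = np.cumsum(self.rates)
        prop = cum[:-1] / self.tfr  # proportion achieved by exact ages 16..49
        if np.any((prop <= 0) | (prop >= 1)):
            raise ValueError("cumulative fertility proportion outside (0,1)")
        return np.arange(16, 50, dtype=float), -np.log(-np.log(prop))

    @classmethod
    def standard(cls) -> "FertilitySchedule":
        """The packaged high-fertility standard, split to single years.

        Five-year rates are integrated to cumulants and interpolated with a
        monotone (PCHIP) spline, the conventional smooth splitting.
        """
        return _fertility_standard_cached()


@functools.lru_cache(maxsize=1)
def _fertility_standard_cached() -> FertilitySchedule:
    tab = _load_packaged_csv("fertility_standard_synthetic.csv")
    ages5 = tab["age"].to_numpy(float)
    rates5 = tab["rate"].to_numpy(float)
    knots = np.concatenate([[15.0], ages5 + 5.0])
    cum = np.concatenate([[0.0], np.cumsum(rates5 * 5.0)])
    spline = PchipInterpolator(knots, cum)
    single = spline(np.arange(15, 51, dtype=float))
    rates = np.diff(single)
    return FertilitySchedule(rates=np.clip(rates, 0.0, None), name="standard-synthetic")


def relational_gompertz_fertility(
    alpha_f: float, beta_f: float, standard: FertilitySchedule | None = None,
    tfr: float | None = None,
) -> FertilitySchedule:
    """Generate a fertility schedule from the relational Gompertz model.

    The standard's cumulated-fertility gompits ``Ys(x)`` are transformed as
    ``Y(x) = alpha_f + beta_f * Ys(x)`` and differenced back to single-year
    rates.  Total fertility is a free scale (defaults to the standard's TFR).
    Raising ``alpha_f`` shifts childbearing earlier; ``beta_f`` controls the
    spread of the schedule.
    """
    if beta_f <= 0:
        raise ValueError("beta_f must be positive")
    std = standard or FertilitySchedule.standard()
    ages, ys = std.gompits()
    y = alpha_f + beta_f * ys
    prop = np.exp(-np.exp(-y))
    cum = np.concatenate([[0.0], prop, [1.0]])  # exact ages 15, 16..49, 50
    rates = np.diff(cum)
    if np.any(rates < -1e-12):
        raise ValueError("transformed cumulants are not monotone")
    rates = np.clip(rates, 0.0, None)
    scale = std.tfr if tfr is None else tfr
    return FertilitySchedule(rates=rates * scale,
                             name=f"gompertz(a={alpha_f},b={beta_f})")


@dataclass(frozen=True)
class StablePopulation:
    """A stable population: schedules, growth rate and implied age structure."""

    life_table: LifeTable
    fertility: FertilitySchedule
    r: float
    age_structure: np.ndarray  # proportion at each single-year age 0..omega+1

    def __post_init__(self):
        if not math.isclose(float(self.age_structure.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("age structure must sum to 1")


def stable_age_structure(
    lt: LifeTable, fert: FertilitySchedule, r: float
) -> StablePopulation:
    """Stable age distribution c(x) ∝ exp(-r x) l(x), normalised to sum 1."""
    if not -0.05 <= r <= 0.05:
        raise ValueError("growth rate outside the supported range [-0.05, 0.05]")
    x = lt.ages
    c = np.exp(-r * x) * lt.lx
    c = c / c.sum()
    return StablePopulation(life_table=lt, fertility=fert, r=r, age_structure=c)


def rate_to_probability(m, n: int = 5, a: float | None = None):
    """Convert a central death rate nmx into the probability nqx.

    q = n*m / (1 + (n - a)*m) with the mid-interval default a = n/2.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("rates must be non-negative")
    if a is None:
        a = n / 2.0
    if not 0 < a < n:
        raise ValueError("average years lived by the dying must be in (0, n)")
    q = n * m / (1.0 + (n - a) * m)
    q = np.clip(q, 0.0, 1.0)
    return float(q) if q.ndim == 0 else q


def chain_q(probabilities) -> float:
    """1 minus the product of interval survival probabilities 1-q or p."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(1.0 - np.prod(p))


def chain_35q15(five_pn, expected_groups: int = 7) -> float:
    """Chain seven 5pn values (ages 15-19 .. 45-49) into 35q15.

    Pass ``expected_groups=None`` to chain over a non-standard age range.
    """
    p = np.asarray(five_pn, dtype=float)
    if expected_groups is not None and len(p) != expected_groups:
        raise ValueError(
            f"expected {expected_groups} five-year survival probabilities, got {len(p)}"
        )
    return chain_q(p)


# ---------------------------------------------------------------------------
# Model life-table family for converting partial survivorship into 35q15
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=4)
def synthetic_west_family(sex: str = "female") -> pd.DataFrame:
    """A SYNTHETIC one-parameter model life-table family indexed by level.

    Stand-in for the Princeton (Coale-Demeny) West family, which is not
    redistributable here: levels 1..25 are generated from the relational logit
    system on the Brass general standard, with the level's alpha solved so that
    e0 matches the West female level spacing e0 = 20 + 2.5*(level-1).  The
    family preserves the *mechanics* of a West lookup (level interpolation on a
    survivorship ratio); its age pattern is the general standard's, so
    converted 35q15 values can deviate from true West values by a few percent.
    """
    levels = np.arange(1, 26)
    rows = []
    for lev in levels:
        e0_target = 20.0 + 2.5 * (lev - 1)

        def gap(alpha):
            return brass_logit_lifetable(alpha, 1.0).e0 - e0_target

        alpha = brentq(gap, -2.5, 2.5, xtol=1e-10)
        lt = brass_logit_lifetable(alpha, 1.0, sex=sex)
        row = {"level": lev, "alpha": alpha, "e0": lt.e0, "q35_15": lt.q35_15}
        for n in range(20, 55, 5):
            row[f"p15_{n}"] = lt.npx(15, n - 15)
        rows.append(row)
    return pd.DataFrame(rows)


def west_model_lookup(p: float, sex: str = "female", n: int = 25) -> tuple[float, bool]:
    """Convert a survivorship ratio n-15p15 into 35q15 via the model family.

    Finds the family level whose ``n-15p15`` matches ``p`` (linear
    interpolation between adjacent levels) and returns that level's 35q15,
    along with a flag that is True when ``p`` fell outside the tabulated range
    and linear extrapolation was used.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("survivorship ratio must be in (0, 1)")
    fam = synthetic_west_family("female" if sex not in ("male", "female") else sex)
    col = f"p15_{n}"
    if col not in fam.columns:
        raise ValueError(f"unsupported upper age {n}; expected one of 20..50")
    pn = fam[col].to_numpy()
    q = fam["q35_15"].to_numpy()
    # pn increases with level while q decreases
    extrapolated = bool(p < pn[0] or p > pn[-1])
    q35 = float(np.interp(p, pn, q))
    if extrapolated:
        if p < pn[0]:
            slope = (q[1] - q[0]) / (pn[1] - pn[0])
            q35 = float(q[0] + slope * (p - pn[0]))
        else:
            slope = (q[-1] - q[-2]) / (pn[-1] - pn[-2])
            q35 = float(q[-1] + slope * (p - pn[-1]))
        q35 = min(max(q35, 0.0), 1.0)
    return q35, extrapolated


# ---------------------------------------------------------------------------
# Stable-population (Lotka) calibration helpers
# ---------------------------------------------------------------------------

def _net_reproduction_integral(lt: LifeTable, fert: FertilitySchedule,
                               r: float, frac_female: float) -> float:
    ages = fert.ages
    # person-years lived in [x, x+1) approximated trapezoidally
    Lx = 0.5 * (lt.lx[ages] + lt.lx[ages + 1])
    mids = ages + 0.5
    return float(np.sum(np.exp(-r * mids) * Lx * fert.rates * frac_female))


def lotka_growth_rate(lt: LifeTable, fert: FertilitySchedule,
                      frac_female: float = 0.488) -> float:
    """Intrinsic growth rate solving the Euler-Lotka equation."""
    def f(r):
        return _net_reproduction_integral(lt, fert, r, frac_female) - 1.0
    return brentq(f, -0.1, 0.15, xtol=1e-12)


def fertility_scale_for_growth(lt: LifeTable, fert: FertilitySchedule,
                               r: float, frac_female: float = 0.488) -> float:
    """Multiplier on the fertility schedule so the Lotka rate equals ``r``."""
    return 1.0 / _net_reproduction_integral(lt, fert, r, frac_female)
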