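# Methods

`sibsurv` estimates adult mortality — principally 35q15, the probability
that a person alive at exact age 15 dies before exact age 50 — from sibling
survival histories (SSH) of the kind collected by Demographic and Health
Surveys. It implements one direct and three indirect estimators, and the
stable-population microsimulation used to derive (and regenerate) the
conversion coefficients behind the recent-deaths indirect method.

## Estimators

**Direct estimation** (`sibsurv.direct`). Full SSH give each sibling's birth
and death dates as century-month codes (CMC, months since January 1900).
Deaths and person-months of exposure are accumulated by 5-year age group
over a reference window of `w` years ending the month before the interview;
the month of death contributes half a month of exposure (switchable). Rates
convert to probabilities by the standard actuarial relation
`5qx = 5·m / (1 + 2.5·m)` (average years lived by those dying, a = n/2),
and `35q15 = 1 − Π(1 − 5qx)` chains the seven age groups. Variance comes
from a stratified leave-one-cluster-out jackknife with the usual
`(n_h − 1)/n_h` scaling and a normal-approximation CI on the probability
scale (log/logit scales would be straightforward variants; the probability
scale is the default because the estimates are far from the boundary in the
intended applications).

**Recent-deaths indirect method** (`sibsurv.indirect.recent_method`). From
three summary questions per sibling sex — siblings who reached 15 (R), of
those the number who died (D), and deaths in the last five years (D5) — one
forms S(t) = (R−D)/R and S(t−5) = (R−D+D5)/R per respondent 5-year age
group, pooled as weight-summed counts (not means of individual ratios, so
the estimator stays defined when some respondents report R = 0). The ratio
S(t)/S(t−5) is the five-year survival of the adult sibling set and converts
to the life-table probability 5pn by per-age-group linear coefficients,
`5pn = β0(n) + β1(n)·ratio`, chained into 35q15 for the 0–4 years before
the survey. Both the published coefficient set and a set regenerated by
this package's own simulations are shipped
(`CoefficientTable.published_recent()` / `.refit_recent()`).

Boundary conventions (configurable, documented here because they decide
ties): a sibling dying in the month of their 15th birthday counts as having
reached 15; a death exactly 60 months before the interview is inside the
window; the reference window is the 60 months ending the month before the
interview.

**Adult lifetime-proportions method** (`lifetime_method`). The proportion
of siblings who reached 15 still alive at the survey converts to the
survivorship n−15p15 with the published linear coefficients for respondents
aged 20–49 (reports from ages 15–19 are discarded: their siblings are on
average older than they are, making the conversion unstable). The
survivorship then maps to 35q15 through a one-parameter model life-table
family, and each age group's estimate is dated some years before the survey
(see *Time location* below).

**Two-survey cohort-change method** (`two_survey_method`). With two surveys
about five years apart, the cohort aged n−5..n at the first survey is aged
(n−5..n)+T at the second; the ratio of its proportions of adult siblings
alive, S2(n)/S1(n−5), plays the same role as the recent-deaths ratio (the
youngest cohort's denominator is 1 — its siblings' adult deaths before the
first survey are negligible by construction of the age groups; this cohort
alignment is inferred from the worked example's arithmetic). At T = 5 the
method coincides *exactly* with the recent-deaths method fed the same
proportions, a tested identity.

*Awkward intervals.* When T ≠ 5, survival over T years converts to the
5-year equivalent under a Gompertz assumption: with the force of mortality
`μ(x) = a·e^{βx}` and both windows starting at the same cohort age,
`ln p5 = ln pT · (e^{5β} − 1)/(e^{Tβ} − 1)`; T = 5 is the identity, and
T < 5 lowers the ratio. The operative β here is the slope of the *sibling
set's* aggregate hazard, which rises far more slowly in age than an
individual's (each respondent group's siblings span ~20 years of age, and
aggregation over a heterogeneous mix flattens the gradient). By default the
slope is therefore estimated from the input's own age gradient by
regressing ln(−ln ratio) on the age-group midpoints (≈0.03/year in the
packaged worked example; clipped to [0, 0.15], fallback 0.05 with fewer
than three informative groups); an explicit slope can be passed, and the
standalone `awkward_interval_adjust` defaults to 0.1/year, a conventional
individual-level adult slope.

**Confidence intervals for indirect estimates** (`indirect_ci`). The
stratified jackknife reruns the whole pipeline (tabulate → convert → chain)
on leave-one-cluster-out replicates; a binomial/delta-method approximation
on the pooled counts is available as a cluster-free alternative.

## Relational schedules and standards

Mortality uses the two-parameter logit system: with `Ys(x) = ½·ln((1−ls)/ls)`
the logits of a standard survivorship curve, `Y(x) = α + β·Ys(x)` generates
a life table; (α, β) = (0, 1) is the standard itself and larger α means
higher mortality. The packaged standard is the Brass general standard
(knots at ages 1–4 yearly, then quinquennial to 85, interpolated linearly
in logits and extended beyond 85 by geometrically growing logit
increments, closing by age 110; e0 ≈ 43.4). Fertility uses the relational
Gompertz model: the double-log transform of the proportion of total
fertility achieved by each age, `−ln(−ln F(x)/TF)`, is shifted and scaled
the same way, with total fertility a free scale. Its packaged standard is
**synthetic**: a high-fertility, natural-fertility-shaped schedule (mean
age ≈ 28.4) constructed for this package because the published standard
table could not be redistributed here; the file is labelled accordingly.
Across the simulation grid (α_m ∈ {−1, −0.6, −0.2, 0.2} × β_m ∈ {0.7, 1.1};
α_f ∈ {−0.5, −0.2, 0.1, 0.4} × β_f ∈ {1, 1.15, 1.4, 1.8}) the generated
life expectancies span 35.5–74.1 years and fertility mean ages 25.6–31.6.

The model life-table family behind `west_model_lookup` is likewise
**synthetic**: 25 levels generated from the logit system on the general
standard, with level ℓ solved to e0 = 20 + 2.5·(ℓ−1) (the female level
spacing of the Princeton West family it stands in for). Lookup mechanics
match the classical procedure — find the level whose n−15p15 equals the
input by linear interpolation, return its 35q15, flag extrapolation — but
the age *pattern* is the general standard's, so converted 35q15 values can
deviate from true West conversions by a few percent (up to ≈8 per 1000 in
the packaged worked example). The lifetime method's survivorship column is
exact; its 35q15 column inherits this conversion error.

## The microsimulation

`sibsurv.microsim` runs a closed population on a monthly clock. Founders
are drawn from the stable age structure `c(x) ∝ e^{−rx} l(x)`; the founding
size is back-projected from the target final size as `N0 = N·e^{−rT}`
(default N = 40,000 after T = 150 years). Deaths: each individual's age at
death is drawn once, at birth, by inverse-CDF sampling of the monthly
survival curve (geometric interpolation of l(x) within years), which is
distributionally identical to month-by-month hazard draws for an age-only
hazard and reproduces the input life table exactly; with year-by-year
period tables (`alpha_m_path`) the draw uses the birth cohort's diagonal
survival curve. Births: every woman aged 15–49 faces the same monthly
hazard regardless of parity, subject only to a minimum inter-birth
interval (default 10 months; sex ratio at birth 0.512 male — both beyond
the level of detail the source methods specify, chosen as conventional
values). Two calibrations make the nominal parameters mean what they say:

* the fertility schedule is pre-scaled so the Euler–Lotka growth rate of
  (life table, schedule, fraction female) equals the configured r; and
* the hazard applied to interval-*eligible* women is inflated by
  `λ = μ/(1 − Σ μ_prev)` where the sum runs over the preceding interval
  months, so the realized population age-specific rates match the schedule
  despite post-birth blocking.

Realized growth rates land within ±0.001 of the target and the headline
configuration reaches its 40,000 survivors within a few percent.
Extinction (possible at high r, where N0 is small) raises a specific
exception carrying the month and seed. The engine is numba-compiled; a
full-scale 150-year run takes well under a second, which is what makes the
coefficient regeneration below routine. Sibling histories are
reconstructed at the end-of-run survey by grouping all persons born in the
simulation on their mother's id; respondents are everyone alive and aged
15–49, each excluded from their own sibling list, with post-survey deaths
censored to "alive".

## Coefficient regeneration

`experiments.refit_recent_coefficients` reruns the derivation of the
recent-deaths coefficients: the full 192-combination design, two seeds per
combination, target final size 16,000 (chosen from a variance analysis:
ratios at this size carry Monte-Carlo noise an order of magnitude below
their cross-design spread). One observation per combination and age group
pairs the seed-averaged ratio with the exact life-table truth
`5pn = l(n+5)/l(n)`; OLS of truth on ratio per age group gives β0, β1.
Because the regressor is a noisy measurement of the design-level ratio,
the slope is corrected for attenuation by the reliability factor
`λ = 1 − (noise variance of the averaged ratio)/(total variance)`,
estimated from the replicate seeds — a textbook errors-in-variables
correction; R² is reported uncorrected. The refit reproduces the published
set to within ±0.05 for ages 20–49 with R² ≈ 0.97 throughout; the 15–19
coefficients land ≈0.09 steeper. That group's ratio is dominated by
siblings entering adulthood during the window, making it the most
sensitive to the fertility standard behind the simulations — with the
synthetic standard the cross-design range of the 15–19 ratio is slightly
compressed, which steepens the fitted slope. For the same reason,
cross-applying the *published* coefficients to this package's simulations
overstates 35q15 by ≈4–6%; validation therefore uses the package's own
refitted set (the self-consistent design), and the published set remains
the default for real survey data.

## Time location

Indirect lifetime estimates refer to some years before the survey. The
packaged dating is measured, not assumed: mortality is held constant and
then drifts linearly in α over the final 40 simulated years; each age
group's lifetime estimate (converted with a mapping fitted on the *stable*
runs, so composition effects cancel) is placed on the known period
schedule, and the lag T(n) where period n−15p15 equalled the estimate is
recorded and regressed on ln(5S) across the grid (slope kept only when
|t| ≥ 2). In this simulation universe the estimates date T ≈ 10–16 years
back for all age groups — substantially longer than the published 3.3–13.9
years, and roughly flat in n. The discrepancy is real, not numerical: a
parity-independent birth process yields a wide sibling age-gap
distribution, so even young respondents' lifetime deficits are dominated
by long-past deaths of much older siblings, whereas the published dating
assumes the empirically narrower birth distribution observed in World
Fertility Survey data. The packaged table (`timing_coefficients.csv`,
regenerable with `scripts/fit_timing.py`) is therefore this package's own
measurement; worked examples display it with that caveat.

## What the synthetic data do and do not show

The microsimulation emulates stable (or smoothly drifting) closed
populations with parity-independent fertility, a single mortality schedule
for both sexes, complete and error-free reporting, and exact dates. Tests
passing on these data demonstrate internal consistency of the estimators —
unbiasedness against a known truth, agreement between independent
computational routes, invariances — but say nothing about survey-world
error sources: omission of dead siblings, misplacement of deaths in time,
age heaping, selection of respondents, or HIV-type crisis age patterns.
The published evaluation of these methods against real surveys is the
evidence on those fronts; this package reproduces the printed worked
examples of that evaluation but cannot rerun it without the restricted
microdata.

## Numerical choices and degenerate inputs

Logit/gompit transforms reject standards with l(x) ∈ {0, 1} or
non-monotone cumulants in their interior. `rate_to_probability` clips to
[0, 1] (saturating at m = 0.4/year for n = 5, a = 2.5). Chaining refuses
age groups with zero exposure rather than imputing. Jackknife strata with
a single cluster are collapsed into the nearest stratum and recorded.
Survey-design weights may be any positive scale; all estimators are
invariant to uniform rescaling (tested). Random runs are reproducible from
a single integer seed; identical configurations and seeds give
byte-identical event logs.

## Known limitations

* The model life-table family and the fertility standard are synthetic
  stand-ins (see above); the lifetime method's 35q15 conversions and the
  youngest group's regenerated coefficients inherit quantified deviations.
* Coefficients and validation cover ages 15–49 and 5-year groups only.
* No marriage, migration, parity-specific fertility, twins, or
  reporting-error models in the simulator.
* The two-survey method supports inter-survey intervals of 3–8 years.
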