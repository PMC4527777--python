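# Methods

## The model

`impact_tfa` is a comparative-risk-assessment model of coronary heart
disease (CHD) outcomes under population-level reductions in dietary
trans-fatty-acid (TFA) intake, stratified by age band, sex and
socio-economic quintile. It computes three outputs per year of a
scenario:

* **Deaths prevented or postponed (DPP).** For stratum *s* with
  expected CHD deaths *D_s* under no intake change,

      DPP_s = D_s × min(Δ_q(s) × MRF_{a(s),x(s)}, 1)

  where Δ_q is the intake reduction (% of daily energy) for the
  stratum's quintile and MRF is the age/sex mortality-reduction factor
  per 1% of energy. The dose-response is linear in Δ up to the cap, so
  a 0.5% reduction yields exactly half the gains of a 1% reduction.

* **Life-years gained (LYG).** Each averted death is attributed to one
  of three CHD states — diagnosed CHD, undiagnosed CHD, free of CHD —
  with age-specific shares π, and weighted by that state's median
  survival:

      LYG_s = DPP_s × [ π_d · S_d(a) + π_u · ½(S_d(a)+S_n(a)) · L_q
                        + π_n · S_n(a) · L_q ]

  Undiagnosed survival is the midpoint of the diagnosed and no-CHD
  medians. L_q is a life-expectancy index per deprivation quintile,
  anchored at exactly 1.0 for quintile 3; it scales the undiagnosed and
  no-CHD survivals only. Diagnosed-CHD survival is deliberately *not*
  deprivation-indexed: population survival data after a CHD diagnosis
  are not stratified by deprivation, so indexing it would fabricate a
  gradient (this likely understates the true inequality in survival).

* **Admissions avoided.** Only incident admission groups — acute
  myocardial infarction (AMI), unstable angina (UA), heart failure
  (HF) — enter; community-prevalence groups are excluded because the
  policy is assumed to have negligible effect on case fatality, hence
  on prevalence. Avoided counts are baseline incident admissions times
  the same relative reduction, which preserves the within-stratum
  AMI:UA:HF ratios by construction.

Inequality results are reported both as crude stratum sums and as
**rate indices**: outcome ÷ quintile population, expressed relative to
quintile 3 (= 1.0 exactly). Rates avoid artefacts from quintile
population differences at older ages, where affluent quintiles retain
more survivors.

## The effect table

The anchor parameter is the population-average relative CHD-mortality
reduction for a 1%-of-energy TFA reduction, **12%** (`base_reduction =
0.12`). The effect attenuates with age, mirroring the attenuation of
the cholesterol–CHD relative risk. The published age/sex factor values
are not redistributable, so the default table is **parametric**: a
non-increasing attenuation schedule (1.00, 0.90, 0.78, 0.65, 0.52,
0.40 for ages 25–34 … 75–84; both sexes share the schedule) is
calibrated by a single multiplier so that the population-weighted mean
MRF equals `base_reduction` exactly. Any externally supplied table
with the same schema (`age_band, sex, mrf_1pct, mrf_low, mrf_high`)
overrides it.

The oldest band (85+), for which no direct estimate exists, is filled
by **continued geometric attenuation**: per sex, `mrf(85+) =
mrf(75–84)² / mrf(65–74)`, i.e. the observed ratio between the two
oldest estimated bands is applied once more. A ratio continuation was
chosen over a linear one because the attenuation acts on a relative
risk; it also can never produce a negative factor.

Sensitivity bounds are 80% and 120% of the central estimates in every
cell, rebuilt after any construction or extrapolation.

## Intake scenarios

Two built-in baselines (% of daily energy, quintile 1 = most affluent):

* **equal** — the survey mean of 1.3% in every quintile (conservative);
* **unequal** — the survey gradient 0.75, 0.87, 1.00, 1.25, 1.50 for
  quintiles 1..5: the most deprived consume roughly twice the TFA of
  the most affluent, so a universal target produces the largest
  reductions where baseline mortality is also highest.

Per-quintile reductions are Δ_q = max(baseline_q − target, 0): a
quintile already below the target neither gains nor loses (increases
in intake are out of scope).

## Uncertainty analysis

Parameter uncertainty is propagated by Monte Carlo (default 5,000
draws, empirical 2.5th/97.5th percentiles; a 10,000-draw 5/95 variant
is available by configuration). Draws are **multiplicative factors on
whole table blocks**, not independent per-cell perturbations:

* one factor for the effect table, because the underlying dose-response
  estimate is a single shared parameter whose uncertainty moves every
  age/sex cell together (independent per-cell draws would average out
  in the totals and understate their uncertainty);
* one factor each for the diagnosed and no-CHD survival columns, with
  the undiagnosed midpoint re-derived per draw; the quintile LE index
  is a structural anchor and is not drawn.

Families: truncated normal for the effect factor (mean at the point,
sd = (high − low)/(2·1.96), truncated at 0) and uniform for survival;
both are selectable per class. Each draw is a pure function of
(seed, draw_id, parameter class) via independent generator streams, so
reruns are bit-identical and adding a parameter class never shifts
existing streams. Confidence intervals are linear-interpolation
percentiles of the per-cell draws; they need not be symmetric about
the point estimate, and the point estimate always comes from the mean
parameters, never from the draws.

A useful consequence of the shared effect factor: the total DPP is
linear in it, so under a uniform factor on (0.8, 1.2) the 2.5th
percentile of total DPP sits at exactly 0.81 × the point estimate —
the test suite checks the Monte Carlo against this closed form.

## Subgroup shares

How averted deaths split across the three CHD states is not
identifiable from published outputs; it is an explicit input
(`SubgroupShares`). The default fixture puts a diagnosed share rising
from 0.25 (ages 25–34) to 0.55 (85+), a flat 0.25 undiagnosed share,
and the remainder CHD-free — prevalent diagnosed disease accumulates
with age. Results that depend on this apportionment (LYG levels, not
DPPs or admissions) should be read with that sensitivity in mind; the
input is a keyword argument everywhere it matters.

## Synthetic baselines

Real inputs (national mortality forecasts, hospital episode counts,
survival cohorts, deprivation life tables) are not redistributable.
The generator (`impact_tfa.synthetic`) produces baselines with the
structure the analysis relies on, at England-and-Wales scale:

| parameter | default | meaning |
|---|---|---|
| `total_population` | 35,000,000 | adults 25+ |
| `total_chd_deaths` | 32,500 / yr | expected CHD deaths in the scenario year |
| `age_mortality_doubling` | 7 yr | age doubling time of the CHD death rate |
| `male_excess` | 1.8 | male/female rate ratio |
| `sec_mortality_ratio` | 1.5 | quintile-5 / quintile-1 rate ratio (log-linear across quintiles) |
| `admission_multipliers` | AMI 0.4, UA 1.7, HF 0.4 | incident admissions per CHD death |
| `survival_anchors` | diagnosed 7 y, none 18 y | medians at ages 65–74 |
| `le_gradient` | 0.16 | LE-index span across quintiles (1.08 … 0.92) |

Age-band population shares thin with age, the female share rises to
0.65 at 85+, and affluent quintiles are mildly over-represented at
older ages. Admission age shapes make UA peak in middle age and HF in
old age while preserving group totals. Stratum deaths are apportioned
to integers by largest remainder, so they sum exactly to the target
and each stratum lands within one death of its real-valued share.

Generation is **deterministic given the spec**: the seed is recorded
for provenance but baselines carry no sampled noise — stochasticity
belongs to the sensitivity analysis, not to the fixtures. The
magnitudes are illustrative (the right orders of magnitude: thousands
of DPPs, tens of thousands of LYG, thousands of avoided admissions per
year for a 1% reduction), never a reproduction of any national
dataset, and passing tests demonstrate the model's structural
properties — linearity, anchoring, conservation, calibration — not
agreement with published national totals. Features of real data the
generator does not emulate: cohort effects, within-stratum
overdispersion, readmissions, secular trends in case fatality.

## Numerical choices

* Counts are non-negative reals (forecast deaths need not be integers).
* Quintile-3 anchors (LE index, rate index) are enforced to 1.0 within
  1e-9 on input and exactly by construction on output.
* Aggregates are exact sums of member strata; display rounding
  (nearest 100; nearest 1,000 above 10,000; ties to even) exists only
  in the presentation tables, never in machine outputs.
* The relative-reduction cap at 1 makes the dose-response piecewise
  linear; all shipped scenarios operate far below the cap.
* Degenerate inputs: zero-width parameter supports return the point
  exactly; a zero quintile-3 rate makes the rate index undefined
  (error in the library, NaN columns in the exported tables for the
  all-zero scenario).

## Problem sizes

The default test and acceptance runs use the full 70-stratum grid with
5,000–50,000 Monte Carlo draws and 1,000 randomized oracle cases;
the complete suite runs in a few minutes on one CPU.

## Known limitations

* No substitution effects: the fat replacing TFA is assumed risk-free.
* No time dynamics: effects are immediate, case fatality and community
  prevalence are frozen, and readmissions within a year are not
  modelled (all conservative for the admissions burden).
* The subgroup apportionment and the attenuation schedule are
  documented fixtures, not estimates; swap in external tables where
  available.
* DPPs are "prevented or postponed": life-years, not immortality.
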