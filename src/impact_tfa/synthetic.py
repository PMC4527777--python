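"""Synthetic England-and-Wales-like baseline generator.

Real inputs to the model (national mortality forecasts, hospital
episode counts, survival studies, deprivation life tables) are not
redistributable, so this module generates baselines with the same
statistical structure the analysis relies on:

* CHD death rates rising steeply with age (a configurable doubling
  time), a male excess, and a monotone deprivation gradient
  (quintile 5, the most deprived, worst);
* a population of ~35 million adults with an age pyramid that thins at
  older ages, a female excess among the old, and mildly
  affluence-tilted survival into old age;
* incident admissions proportional to expected deaths with
  group-specific age shapes (unstable angina peaking mid-age, heart
  failure in old age);
* median survival decreasing with age and ordered none >= undiagnosed
  (midpoint) >= diagnosed, with a linear life-expectancy index across
  quintiles anchored at 1.0 for quintile 3.

Generation is deterministic given the spec: the seed is recorded for
provenance but baselines carry no sampled noise — stochasticity belongs
to the sensitivity analysis, not the fixtures.  Magnitudes default to
the England-and-Wales scale (tens of thousands of CHD deaths a year) so
scenario outputs are order-of-magnitude realistic; they are
illustrative, never a reproduction of any national dataset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .strata import (
    AGE_BANDS,
    DISEASE_GROUPS,
    QUINTILES,
    SEXES,
    AdmissionsBaseline,
    BaselineScenario,
    SurvivalTable,
    ValidationError,
    stratum_index,
    write_admissions,
    write_baseline,
    write_survival,
)

# age-band structure shared by the generators
_AGE_MIDPOINTS = np.array([29.5, 39.5, 49.5, 59.5, 69.5, 79.5, 89.5])
_AGE_POP_SHARE = np.array([0.17, 0.17, 0.18, 0.16, 0.14, 0.11, 0.07])
_FEMALE_SHARE = np.array([0.50, 0.50, 0.50, 0.51, 0.52, 0.55, 0.65])
#: Affluent quintiles retain more survivors into old age.
_QUINTILE_AGE_TILT = np.array([0.0, 0.0, 0.05, 0.10, 0.15, 0.25, 0.35])

#: Disease-group age shapes (relative, renormalised against the death
#: distribution): UA peaks in middle age, HF in old age.
_GROUP_AGE_SHAPE = {
    "AMI": np.array([0.5, 0.8, 1.2, 1.4, 1.3, 1.0, 0.7]),
    "UA": np.array([0.6, 1.0, 1.5, 1.6, 1.3, 0.9, 0.5]),
    "HF": np.array([0.1, 0.2, 0.4, 0.7, 1.1, 1.6, 2.0]),
}

#: Median-survival age shape relative to the 65-74 anchor band.
_SURVIVAL_SHAPE = np.array([3.0, 2.5, 2.0, 1.45, 1.0, 0.62, 0.33])
_ANCHOR_BAND = "65-74"


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic baseline.

    Defaults are the study conditions: ~35M adults, 32,500 expected CHD
    deaths in the scenario year, death rates doubling every 7 years of
    age, a 1.8x male excess, a 1.5x most-deprived/most-affluent
    mortality rate ratio, admissions multipliers of 0.4/1.7/0.4
    (AMI/UA/HF) incident admissions per CHD death, survival anchors of
    7y (diagnosed) and 18y (no CHD) at ages 65-74, and a 0.16
    life-expectancy-index span across quintiles.
    """

    seed: int = 0
    total_population: float = 35_000_000
    total_chd_deaths: float = 32_500
    age_mortality_doubling: float = 7.0
    male_excess: float = 1.8
    sec_mortality_ratio: float = 1.5
    admission_multipliers: dict[str, float] = field(
        default_factory=lambda: {"AMI": 0.4, "UA": 1.7, "HF": 0.4}
    )
    survival_anchors: dict[str, float] = field(
        default_factory=lambda: {"diagnosed": 7.0, "none": 18.0}
    )
    le_gradient: float = 0.16
    year_label: str = "2030"

    def validate(self) -> "SyntheticSpec":
        if self.total_population <= 0 or self.total_chd_deaths < 0:
            raise ValidationError("population must be positive, deaths non-negative")
        if self.total_chd_deaths >= self.total_population:
            raise ValidationError("total deaths must be below total population")
        for name in ("age_mortality_doubling", "male_excess", "sec_mortality_ratio"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for g, m in self.admission_multipliers.items():
            if m < 0:
                raise ValidationError(f"admission multiplier for {g!r} must be >= 0")
        if self.survival_anchors["none"] < self.survival_anchors["diagnosed"]:
            raise ValidationError(
                "no-CHD survival anchor must be >= diagnosed anchor "
                "(state ordering would be violated)"
            )
        if self.le_gradient < 0:
            raise ValidationError("le_gradient must be >= 0")
        return self


def _largest_remainder(raw: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``raw``
    (largest-remainder method); each cell lands within 1 of its real
    target."""
    raw = np.asarray(raw, dtype=float)
    if raw.sum() <= 0:
        return np.zeros_like(raw, dtype=np.int64)
    target = raw * (total / raw.sum())
    floors = np.floor(target).astype(np.int64)
    shortfall = int(round(total - floors.sum()))
    order = np.argsort(-(target - floors), kind="stable")
    floors[order[:shortfall]] += 1
    return floors


def _structure_arrays(spec: SyntheticSpec):
    """Population and death-rate arrays on the 70-stratum grid,
    in canonical stratum order."""
    idx = stratum_index()
    n_a, n_s, n_q = len(AGE_BANDS), len(SEXES), len(QUINTILES)

    # population: age share x sex share x tilted quintile share
    sex_share = np.stack([1.0 - _FEMALE_SHARE, _FEMALE_SHARE], axis=1)  # (age, sex)
    q_offsets = 3 - np.array(QUINTILES, dtype=float)  # +2 .. -2
    q_weight = 1.0 + _QUINTILE_AGE_TILT[:, None] * q_offsets[None, :] / 2.0  # (age, q)
    q_share = q_weight / q_weight.sum(axis=1, keepdims=True)
    pop = (
        spec.total_population
        * _AGE_POP_SHARE[:, None, None]
        * sex_share[:, :, None]
        * q_share[:, None, :]
    )  # (age, sex, q)

    # death rates: exponential in age, male excess, log-linear SEC gradient
    age_factor = 2.0 ** ((_AGE_MIDPOINTS - 70.0) / spec.age_mortality_doubling)
    sex_factor = np.array([spec.male_excess, 1.0])
    q_factor = spec.sec_mortality_ratio ** ((np.array(QUINTILES) - 1) / 4.0)
    rate = age_factor[:, None, None] * sex_factor[None, :, None] * q_factor[None, None, :]
    return idx, pop.reshape(-1), rate.reshape(-1)


def generate_baseline(spec: SyntheticSpec) -> BaselineScenario:
    """Deterministic stratified population and expected CHD deaths.

    Stratum deaths are apportioned to integers by largest remainder so
    they sum exactly to ``total_chd_deaths``.
    """
    spec.validate()
    idx, pop, rate = _structure_arrays(spec)
    population = _largest_remainder(pop, int(round(spec.total_population))).astype(float)
    deaths_raw = pop * rate
    deaths = _largest_remainder(deaths_raw, int(round(spec.total_chd_deaths))).astype(float)
    if (deaths > population).any():
        raise ValidationError(
            "infeasible spec: expected deaths exceed population in a stratum"
        )
    data = pd.DataFrame(
        {"expected_deaths": deaths, "population": population}, index=idx
    )
    return BaselineScenario(data=data, year_label=spec.year_label).validate()


def generate_admissions(
    spec: SyntheticSpec, baseline: BaselineScenario
) -> AdmissionsBaseline:
    """Incident admissions proportional to expected deaths.

    Each group's age shape is renormalised against the death
    distribution, so group totals are exactly multiplier x total deaths
    before integer rounding.
    """
    spec.validate()
    deaths = baseline.data["expected_deaths"].to_numpy()
    age_pos = np.array(
        [AGE_BANDS.index(b) for b in baseline.data.index.get_level_values("age_band")]
    )
    total_deaths = deaths.sum()
    cols = {}
    for g in DISEASE_GROUPS:
        mult = spec.admission_multipliers.get(g, 0.0)
        if mult < 0:
            raise ValidationError(f"admission multiplier for {g!r} must be >= 0")
        shape = _GROUP_AGE_SHAPE[g][age_pos]
        if total_deaths > 0 and (deaths * shape).sum() > 0:
            norm = (deaths * shape).sum() / total_deaths
            raw = deaths * mult * shape / norm
        else:
            raw = np.zeros_like(deaths)
        cols[g] = np.rint(raw)
    data = pd.DataFrame(cols, index=baseline.data.index)
    return AdmissionsBaseline(data=data).validate()


def generate_survival(spec: SyntheticSpec) -> SurvivalTable:
    """Median survival by age and CHD state plus the quintile LE index.

    Survival declines with age following a fixed shape anchored at the
    65-74 band; the undiagnosed state is the midpoint of diagnosed and
    no-CHD.  The LE index is linear across quintiles, spanning
    ``le_gradient`` and anchored at exactly 1.0 for quintile 3.
    """
    spec.validate()
    diagnosed = spec.survival_anchors["diagnosed"] * _SURVIVAL_SHAPE
    none = spec.survival_anchors["none"] * _SURVIVAL_SHAPE
    ms = pd.DataFrame(
        {
            "diagnosed": diagnosed,
            "undiagnosed": 0.5 * (diagnosed + none),
            "none": none,
        },
        index=pd.Index(AGE_BANDS, name="age_band"),
    )
    slope = spec.le_gradient / 4.0
    le = pd.Series(
        {q: 1.0 + slope * (3 - q) for q in QUINTILES}, name="le_index"
    ).rename_axis("sec_quintile")
    return SurvivalTable(median_survival=ms, le_index=le).validate()


def age_standardised_sec_ratio(baseline: BaselineScenario) -> float:
    """Most-deprived / most-affluent CHD death rate ratio, directly
    standardised to the whole population's age-sex structure."""
    df = baseline.data
    pop_as = df["population"].groupby(level=["age_band", "sex"]).sum()
    rates = {}
    for q in (1, 5):
        sub = df.xs(q, level="sec_quintile")
        r = sub["expected_deaths"] / sub["population"]
        rates[q] = float((r * pop_as.reindex(r.index)).sum() / pop_as.sum())
    if rates[1] == 0:
        raise ValidationError("standardised rate ratio undefined: quintile-1 rate is zero")
    return rates[5] / rates[1]


def write_dataset(spec: SyntheticSpec, outdir) -> dict[str, str]:
    """Generate and write baseline.csv, admissions.csv, survival.csv,
    le_index.csv and a provenance JSON of the spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    baseline = generate_baseline(spec)
    admissions = generate_admissions(spec, baseline)
    survival = generate_survival(spec)
    paths = {
        "baseline": outdir / "baseline.csv",
        "admissions": outdir / "admissions.csv",
        "survival": outdir / "survival.csv",
        "le_index": outdir / "le_index.csv",
        "spec": outdir / "synthetic_spec.json",
    }
    write_baseline(baseline, paths["baseline"])
    write_admissions(admissions, paths["admissions"])
    write_survival(survival, paths["survival"], paths["le_index"])
    with open(paths["spec"], "w") as fh:
        json.dump(dataclasses.asdict(spec), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
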