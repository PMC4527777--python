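"""Mortality-reduction factors and trans-fat intake scenarios.

The causal core of the model is a single epidemiological quantity: the
relative reduction in CHD mortality produced by a 1 percentage-point
(of daily energy) reduction in trans-fatty-acid intake, on average 12%
across the adult population.  That average effect attenuates with age,
mirroring the attenuation of the cholesterol-CHD relative risk, so the
working object is an age x sex table of mortality-reduction factors
(MRFs).  A linear dose-response links any intake reduction delta (in %
daily energy) to a relative mortality reduction delta x MRF, capped at
1.  Upper and lower bounds for sensitivity analysis are 120% and 80% of
the central estimates.

The published age/sex factor values live in an unavailable supplement,
so the default table here is parametric: a configurable attenuation
schedule calibrated so the population-weighted mean MRF equals the 12%
anchor.  Any externally supplied table with the same schema overrides
it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .strata import (
    AGE_BANDS,
    QUINTILES,
    SEXES,
    BaselineScenario,
    SchemaError,
    ValidationError,
)

#: Relative CHD mortality reduction for a 1%-of-energy TFA reduction,
#: population average.
DEFAULT_BASE_REDUCTION = 0.12

#: Sensitivity bounds as fractions of the central estimate.
BOUND_LOW_FACTOR = 0.8
BOUND_HIGH_FACTOR = 1.2

#: Default relative attenuation of the effect with age (youngest = 1).
#: Shape mirrors the age attenuation of the cholesterol-CHD relative
#: risk; the 85+ value continues the 75-84 : 65-74 geometric ratio.
DEFAULT_ATTENUATION: dict[str, float] = {
    "25-34": 1.00,
    "35-44": 0.90,
    "45-54": 0.78,
    "55-64": 0.65,
    "65-74": 0.52,
    "75-84": 0.40,
}
DEFAULT_ATTENUATION["85+"] = (
    DEFAULT_ATTENUATION["75-84"] ** 2 / DEFAULT_ATTENUATION["65-74"]
)

#: Mean TFA intake (% daily energy) when intake is assumed equal across
#: deprivation quintiles.
EQUAL_BASELINE_INTAKE = 1.3

#: Unequal baseline intake gradient (% daily energy) by quintile,
#: 1 = most affluent .. 5 = most deprived.
UNEQUAL_BASELINE_INTAKE: dict[int, float] = {1: 0.75, 2: 0.87, 3: 1.0, 4: 1.25, 5: 1.5}


@dataclass
class EffectTable:
    """Age x sex mortality-reduction factors with sensitivity bounds.

    ``data`` is indexed by (age_band, sex) with columns ``mrf_1pct``
    (central), ``mrf_low`` (80%) and ``mrf_high`` (120%).
    """

    data: pd.DataFrame

    def validate(self) -> "EffectTable":
        df = self.data
        for col in ("mrf_1pct", "mrf_low", "mrf_high"):
            if col not in df.columns:
                raise SchemaError(f"effect table: missing column {col!r}")
        if df.index.names != ["age_band", "sex"]:
            raise SchemaError("effect table: index levels must be (age_band, sex)")
        if ((df["mrf_1pct"] < 0) | (df["mrf_high"] >= 1)).any():
            raise ValidationError("effect table: require 0 <= mrf and mrf_high < 1")
        point = df["mrf_1pct"].to_numpy()
        if not (
            np.allclose(df["mrf_low"], BOUND_LOW_FACTOR * point, rtol=0, atol=1e-12)
            and np.allclose(df["mrf_high"], BOUND_HIGH_FACTOR * point, rtol=0, atol=1e-12)
        ):
            raise ValidationError(
                "effect table: bounds must be 80%/120% of the central estimates"
            )
        for sex in df.index.get_level_values("sex").unique():
            bands = [b for b in AGE_BANDS if (b, sex) in df.index]
            vals = df.loc[[(b, sex) for b in bands], "mrf_1pct"].to_numpy()
            if np.any(np.diff(vals) > 1e-12):
                raise ValidationError(
                    f"effect table: mrf must be non-increasing with age (sex={sex})"
                )
        return self

    @property
    def age_bands(self) -> list[str]:
        present = set(self.data.index.get_level_values("age_band"))
        return [b for b in AGE_BANDS if b in present]


def _with_bounds(point: pd.Series) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mrf_1pct": point,
            "mrf_low": BOUND_LOW_FACTOR * point,
            "mrf_high": BOUND_HIGH_FACTOR * point,
        }
    )


def build_effect_table(
    base_reduction: float = DEFAULT_BASE_REDUCTION,
    attenuation_schedule: Mapping[str, float] | None = None,
    population_weights: pd.Series | None = None,
) -> EffectTable:
    """Construct an MRF table anchored to a population-average effect.

    Parameters
    ----------
    base_reduction
        Population-weighted mean relative mortality reduction for a 1%
        TFA-energy reduction (default 0.12).
    attenuation_schedule
        Per-age multipliers (youngest-relative), positive and
        non-increasing with age, keyed by a contiguous prefix of the age
        bands.  Identical for both sexes unless an external table is
        supplied instead.
    population_weights
        Weights per (age_band, sex) summing to 1, used for the
        calibration; uniform by default.

    The returned table satisfies
    ``sum(w * mrf_1pct) == base_reduction`` exactly (to rounding) and
    carries 80%/120% bounds.
    """
    if not 0 < base_reduction < 1:
        raise ValidationError("base_reduction must be in (0, 1)")
    sched = dict(attenuation_schedule or DEFAULT_ATTENUATION)
    unknown = sorted(set(sched) - set(AGE_BANDS))
    if unknown:
        raise SchemaError(f"attenuation schedule: unknown age band {unknown[0]!r}")
    bands = [b for b in AGE_BANDS if b in sched]
    if bands != list(AGE_BANDS[: len(bands)]):
        raise SchemaError("attenuation schedule must cover a contiguous run of "
                          "age bands starting from the youngest")
    mult = np.array([sched[b] for b in bands], dtype=float)
    if (mult <= 0).any():
        raise ValidationError("attenuation multipliers must be positive")
    if np.any(np.diff(mult) > 1e-12):
        raise ValidationError("attenuation schedule must be non-increasing with age")

    idx = pd.MultiIndex.from_product([bands, SEXES], names=["age_band", "sex"])
    if population_weights is None:
        weights = pd.Series(1.0 / len(idx), index=idx)
    else:
        weights = population_weights.reindex(idx)
        if weights.isna().any():
            raise SchemaError("population_weights must cover every (age_band, sex) cell")
        if (weights < 0).any():
            raise ValidationError("population_weights must be non-negative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValidationError("population_weights must sum to 1")
    sched_cells = pd.Series(
        [sched[b] for b in idx.get_level_values("age_band")], index=idx
    )
    denom = float((weights * sched_cells).sum())
    if denom <= 0:
        raise ValidationError(
            "population weights give a zero weighted schedule; the mean effect "
            "cannot be reproduced"
        )
    scale = base_reduction / denom
    point = scale * sched_cells
    if (BOUND_HIGH_FACTOR * point >= 1).any():
        raise ValidationError("calibrated mrf_high reaches 1; schedule infeasible")
    return EffectTable(data=_with_bounds(point)).validate()


def extrapolate_oldest_band(table: EffectTable) -> EffectTable:
    """Extend a table lacking an 85+ row by continued geometric attenuation.

    Per sex, the 85+ factor continues the observed attenuation ratio:
    ``mrf(85+) = mrf(75-84) * mrf(75-84) / mrf(65-74)``, i.e. the same
    relative-risk attenuation with age continues into the oldest band.
    Bounds are rebuilt at 80%/120%.
    """
    df = table.data
    if "85+" in df.index.get_level_values("age_band"):
        raise ValidationError("table already has an 85+ row")
    new_rows = {}
    for sex in SEXES:
        for band in ("65-74", "75-84"):
            if (band, sex) not in df.index:
                raise SchemaError(
                    f"extrapolation needs the ({band}, {sex}) row"
                )
        m65 = float(df.loc[("65-74", sex), "mrf_1pct"])
        m75 = float(df.loc[("75-84", sex), "mrf_1pct"])
        if m65 == 0:
            if m75 > 0:
                raise ValidationError(
                    f"attenuation ratio undefined for sex={sex}: "
                    "mrf(65-74)=0 with mrf(75-84)>0"
                )
            new_rows[("85+", sex)] = 0.0
        else:
            new_rows[("85+", sex)] = max(m75 * (m75 / m65), 0.0)
    point = pd.concat(
        [df["mrf_1pct"], pd.Series(new_rows)]
    )
    point.index = pd.MultiIndex.from_tuples(point.index, names=["age_band", "sex"])
    order = [
        (b, s) for b in AGE_BANDS for s in SEXES if (b, s) in point.index
    ]
    point = point.loc[order]
    return EffectTable(data=_with_bounds(point)).validate()


def scale_effect(table: EffectTable, delta: float, column: str = "mrf_1pct") -> pd.Series:
    """Relative mortality reduction for an intake reduction of ``delta``
    % daily energy, by (age_band, sex): linear dose-response,
    ``delta * mrf``, capped at 1."""
    if delta < 0:
        raise ValidationError(
            "delta must be non-negative: only intake reductions are modelled"
        )
    return np.minimum(delta * table.data[column], 1.0).rename("mrf")


@dataclass
class IntakeScenario:
    """Baseline and target TFA intake (% daily energy) per quintile.

    ``delta`` is the implied per-quintile reduction, floored at 0 (an
    already-low quintile cannot gain from a target above its baseline).
    """

    name: str
    baseline_intake: pd.Series
    target_intake: pd.Series

    @property
    def delta(self) -> pd.Series:
        return (self.baseline_intake - self.target_intake).clip(lower=0.0).rename("delta")

    def validate(self) -> "IntakeScenario":
        for s in (self.baseline_intake, self.target_intake):
            missing = [q for q in QUINTILES if q not in s.index]
            if missing:
                raise SchemaError(f"scenario {self.name!r}: missing quintile {missing[0]}")
            if (s.reindex(list(QUINTILES)) < 0).any():
                raise ValidationError(f"scenario {self.name!r}: intakes must be >= 0")
        if self.name == "equal" and self.baseline_intake.nunique() != 1:
            raise ValidationError("equal scenario requires identical baseline intake "
                                  "across quintiles")
        return self


_SCENARIO_ALIASES = {
    "equal": "equal",
    "tfasec1_equal": "equal",
    "tfasec1": "equal",
    "unequal": "unequal",
    "tfasec2_unequal": "unequal",
    "tfasec2": "unequal",
    "custom": "custom",
}


def build_intake_scenario(
    kind: str,
    target_intake: float | Mapping[int, float] = 0.0,
    baseline_intake: Mapping[int, float] | None = None,
) -> IntakeScenario:
    """Build a per-quintile intake scenario.

    ``equal`` assigns the common 1.3% mean intake to every quintile;
    ``unequal`` assigns the survey-based gradient (0.75, 0.87, 1.0,
    1.25, 1.5 for quintiles 1..5, most affluent to most deprived);
    ``custom`` requires an explicit per-quintile baseline.
    """
    key = _SCENARIO_ALIASES.get(str(kind).lower())
    if key is None:
        raise SchemaError(f"unknown scenario kind {kind!r}")
    if key == "equal":
        base = {q: EQUAL_BASELINE_INTAKE for q in QUINTILES}
    elif key == "unequal":
        base = dict(UNEQUAL_BASELINE_INTAKE)
    else:
        if baseline_intake is None:
            raise SchemaError("custom scenario requires baseline_intake per quintile")
        base = dict(baseline_intake)
    if isinstance(target_intake, Mapping):
        target = dict(target_intake)
    else:
        if target_intake < 0:
            raise ValidationError("target_intake must be >= 0")
        target = {q: float(target_intake) for q in QUINTILES}
    baseline_s = pd.Series(base, name="baseline_intake").rename_axis("sec_quintile")
    target_s = pd.Series(target, name="target_intake").rename_axis("sec_quintile")
    return IntakeScenario(
        name=key, baseline_intake=baseline_s.astype(float), target_intake=target_s.astype(float)
    ).validate()


def population_weights(baseline: BaselineScenario) -> pd.Series:
    """Population shares per (age_band, sex), for effect-table calibration."""
    pop = baseline.data["population"].groupby(level=["age_band", "sex"]).sum()
    return (pop / pop.sum()).rename("weight")
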