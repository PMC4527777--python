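"""Counterfactual outcome computations.

Given a baseline scenario (expected CHD deaths per stratum with no
intake change), an effect table and an intake scenario, the engine
computes per-stratum:

* deaths prevented or postponed (DPP): expected deaths times the
  relative mortality reduction for the stratum's quintile-specific
  intake reduction;
* life-years gained (LYG): DPPs weighted by the median survival of the
  CHD-state subgroup in which the death was averted (diagnosed CHD,
  undiagnosed CHD, free of CHD), with the undiagnosed state at the
  midpoint of the other two and deprivation-scaled survival for the
  undiagnosed/no-CHD states only;
* incident admissions avoided (AMI, UA, HF): baseline incident
  admissions times the same relative reduction, which preserves the
  baseline disease-group ratios within each stratum.

Aggregation and quintile rate indices (anchored at 1.0 for quintile 3)
round out the module.  Case fatality and community prevalence are held
constant: there is no prevalence feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strata import (
    AGE_BANDS,
    CHD_STATES,
    DEFAULT_AGE_GROUPING,
    DISEASE_GROUPS,
    AdmissionsBaseline,
    AgeGrouping,
    BaselineScenario,
    SchemaError,
    SurvivalTable,
    ValidationError,
)
from .effects import EffectTable, IntakeScenario, scale_effect


@dataclass
class SubgroupShares:
    """Apportionment of prevented deaths across CHD states, by age band.

    How averted deaths split between people with diagnosed CHD,
    undiagnosed CHD and no CHD is not observable; it is an explicit
    model input with rows summing to 1 per age band.  The default has
    the diagnosed share rising with age (prevalent disease accumulates)
    and is a documented fixture, not an estimate.
    """

    data: pd.DataFrame

    def validate(self) -> "SubgroupShares":
        df = self.data
        for state in CHD_STATES:
            if state not in df.columns:
                raise SchemaError(f"subgroup shares: missing state column {state!r}")
        missing = [b for b in AGE_BANDS if b not in df.index]
        if missing:
            raise SchemaError(f"subgroup shares: missing age band {missing[0]!r}")
        vals = df.loc[list(AGE_BANDS), list(CHD_STATES)]
        if ((vals < 0) | (vals > 1)).any().any():
            raise ValidationError("subgroup shares must lie in [0, 1]")
        sums = vals.sum(axis=1)
        bad = sums.index[np.abs(sums - 1.0) > 1e-9]
        if len(bad):
            raise ValidationError(
                f"subgroup shares must sum to 1 within each age band; "
                f"violated at {bad[0]!r} (sum={sums[bad[0]]:.6f})"
            )
        return self


def default_subgroup_shares() -> SubgroupShares:
    """Default apportionment: diagnosed share rising with age."""
    diagnosed = [0.25, 0.30, 0.35, 0.40, 0.45, 0.50, 0.55]
    undiagnosed = [0.25] * 7
    df = pd.DataFrame(
        {
            "diagnosed": diagnosed,
            "undiagnosed": undiagnosed,
            "none": 1.0 - np.asarray(diagnosed) - np.asarray(undiagnosed),
        },
        index=pd.Index(AGE_BANDS, name="age_band"),
    )
    return SubgroupShares(data=df).validate()


def _stratum_mrf(
    index: pd.MultiIndex, effect: EffectTable, scenario: IntakeScenario
) -> np.ndarray:
    """Relative mortality reduction per stratum (delta x mrf, capped at 1)."""
    age = index.get_level_values("age_band")
    sex = index.get_level_values("sex")
    q = index.get_level_values("sec_quintile")
    cell = pd.MultiIndex.from_arrays([age, sex], names=["age_band", "sex"])
    mrf = effect.data["mrf_1pct"].reindex(cell)
    if mrf.isna().any():
        bad = cell[mrf.isna()][0]
        raise SchemaError(f"effect table has no row for (age_band, sex) = {bad}")
    delta = scenario.delta.reindex(q)
    if delta.isna().any():
        raise SchemaError("scenario does not define a delta for every quintile")
    return np.minimum(delta.to_numpy() * mrf.to_numpy(), 1.0)


def compute_dpp(
    baseline: BaselineScenario, effect: EffectTable, scenario: IntakeScenario
) -> pd.Series:
    """Deaths prevented or postponed per stratum and year."""
    reduction = _stratum_mrf(baseline.data.index, effect, scenario)
    dpp = baseline.data["expected_deaths"].to_numpy() * reduction
    return pd.Series(dpp, index=baseline.data.index, name="dpp")


def _effective_survival(
    index: pd.MultiIndex, survival: SurvivalTable, shares: SubgroupShares
) -> np.ndarray:
    """Share-weighted median survival per stratum.

    Undiagnosed-state survival is the midpoint of the diagnosed and
    no-CHD medians; the life-expectancy index of the stratum's quintile
    scales the undiagnosed and no-CHD survivals but NOT diagnosed-CHD
    survival (survival after diagnosis is not deprivation-stratified).
    """
    age = index.get_level_values("age_band")
    q = index.get_level_values("sec_quintile")
    ms = survival.median_survival
    surv_diag = ms["diagnosed"].reindex(age).to_numpy()
    surv_none = ms["none"].reindex(age).to_numpy()
    le = survival.le_index.reindex(q).to_numpy()
    sh = shares.validate().data.reindex(age)
    sh_d = sh["diagnosed"].to_numpy()
    sh_u = sh["undiagnosed"].to_numpy()
    sh_n = sh["none"].to_numpy()
    surv_undiag = 0.5 * (surv_diag + surv_none)
    return sh_d * surv_diag + sh_u * (surv_undiag * le) + sh_n * (surv_none * le)


def compute_lyg(
    dpp: pd.Series, survival: SurvivalTable, shares: SubgroupShares
) -> pd.Series:
    """Life-years gained per stratum and year."""
    eff = _effective_survival(dpp.index, survival, shares)
    return pd.Series(dpp.to_numpy() * eff, index=dpp.index, name="lyg")


def compute_admissions_avoided(
    admissions: AdmissionsBaseline, effect: EffectTable, scenario: IntakeScenario
) -> pd.DataFrame:
    """Incident admissions avoided per stratum and disease group.

    Within a stratum the avoided counts inherit the baseline AMI:UA:HF
    ratios: each group is scaled by the same relative reduction.
    """
    unknown = [c for c in admissions.data.columns if c not in DISEASE_GROUPS]
    if unknown:
        raise SchemaError(f"admissions: unknown disease group {unknown[0]!r}")
    reduction = _stratum_mrf(admissions.data.index, effect, scenario)
    return admissions.data.mul(reduction, axis=0)


@dataclass
class OutcomeResults:
    """Per-stratum point results for one scenario, with optional CIs."""

    dpp: pd.Series
    lyg: pd.Series
    admissions_avoided: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        """All metrics side by side, one row per stratum."""
        return pd.concat(
            [self.dpp, self.lyg, self.admissions_avoided], axis=1
        )

    def totals(self) -> dict[str, float]:
        out = {"dpp": float(self.dpp.sum()), "lyg": float(self.lyg.sum())}
        for g in DISEASE_GROUPS:
            out[g] = float(self.admissions_avoided[g].sum())
        out["admissions"] = float(self.admissions_avoided.to_numpy().sum())
        return out


def run_point(
    baseline: BaselineScenario,
    admissions: AdmissionsBaseline,
    survival: SurvivalTable,
    effect: EffectTable,
    scenario: IntakeScenario,
    shares: SubgroupShares | None = None,
) -> OutcomeResults:
    """Point-estimate pipeline: DPP, LYG and admissions avoided."""
    shares = shares or default_subgroup_shares()
    dpp = compute_dpp(baseline, effect, scenario)
    lyg = compute_lyg(dpp, survival, shares)
    avoided = compute_admissions_avoided(admissions, effect, scenario)
    return OutcomeResults(
        dpp=dpp,
        lyg=lyg,
        admissions_avoided=avoided,
        meta={"scenario": scenario.name},
    )


def aggregate(
    values: pd.Series | pd.DataFrame,
    by: list[str],
    grouping: AgeGrouping = DEFAULT_AGE_GROUPING,
) -> pd.Series | pd.DataFrame:
    """Sum stratum-level values over groups.

    ``by`` may mix the stratum levels (age_band, sex, sec_quintile) with
    the pseudo-level ``coarse_band`` (<55 / 55-74 / >=75 via the age
    grouping).  Aggregates are exact sums of member strata.
    """
    grouping.validate()
    keys = []
    for level in by:
        if level == "coarse_band":
            coarse = grouping.coarse(values.index.get_level_values("age_band"))
            keys.append(pd.Index(coarse, name="coarse_band"))
        elif level in values.index.names:
            keys.append(values.index.get_level_values(level))
        else:
            raise SchemaError(f"unknown grouping level {level!r}")
    return values.groupby(keys).sum()


def compute_rate_index(
    values: pd.Series,
    population: pd.Series,
    by: list[str] | None = None,
    grouping: AgeGrouping = DEFAULT_AGE_GROUPING,
) -> pd.DataFrame:
    """Quintile outcome rates and their index anchored at quintile 3.

    Rates divide summed outcomes by the summed population of the same
    quintile (within each requested age/sex group); the index is the
    rate relative to quintile 3, which equals 1.0 exactly by
    construction.  Rates rather than crude numbers avoid artefacts from
    quintile population differences at older ages.
    """
    by = list(by or [])
    levels = by + ["sec_quintile"]
    num = aggregate(values, levels, grouping)
    den = aggregate(population, levels, grouping)
    rate = (num / den).rename("rate")
    if not by:
        anchor = rate.loc[3]
        if anchor == 0:
            raise ValidationError("rate index undefined: quintile-3 rate is zero")
        index = rate / anchor
    else:
        anchor = rate.xs(3, level="sec_quintile")
        if (anchor == 0).any():
            raise ValidationError("rate index undefined: quintile-3 rate is zero "
                                  "in at least one group")
        index = rate / anchor.reindex(rate.droplevel("sec_quintile").index).to_numpy()
    return pd.DataFrame({"rate": rate, "index": index.rename("index")})


def round_display(value: float) -> float:
    """Presentation rounding for totals: nearest 100, nearest 1,000 above
    10,000 (ties to even).  Machine outputs stay unrounded."""
    if abs(value) > 10_000:
        return 1000.0 * round(value / 1000.0)
    return 100.0 * round(value / 100.0)
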