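"""Probabilistic sensitivity analysis (PSA).

Parameter uncertainty is propagated by Monte Carlo: the model is
re-evaluated for each of ``n_draws`` parameter sets drawn from the
declared distributions, and empirical percentiles of every output cell
form the confidence interval.  Defaults follow the model's published
settings: 5,000 draws and the 2.5th/97.5th percentiles (a 10,000-draw,
5/95 variant is available by configuration).

Uncertain quantities are drawn as multiplicative factors applied to
whole table blocks, not independently per cell:

* one factor for the mortality-effect table (the underlying
  dose-response estimate is a single shared parameter; its uncertainty
  moves every age/sex cell together), supported on the table's 80%/120%
  bounds;
* one factor each for diagnosed-CHD and no-CHD median survival, with
  undiagnosed survival recomputed as their midpoint.

Draws are indexed by (seed, draw_id, parameter class), so the same
(seed, draw_id) always reproduces the same parameter set and adding a
parameter class never shifts existing streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .strata import (
    DISEASE_GROUPS,
    AdmissionsBaseline,
    BaselineScenario,
    SchemaError,
    SurvivalTable,
    ValidationError,
)
from .effects import (
    BOUND_HIGH_FACTOR,
    BOUND_LOW_FACTOR,
    EffectTable,
    IntakeScenario,
    _with_bounds,
)
from .outcomes import (
    OutcomeResults,
    SubgroupShares,
    _effective_survival,
    _stratum_mrf,
    default_subgroup_shares,
    run_point,
)

FAMILIES = ("uniform", "normal-truncated")

# Stable per-class stream offsets; new parameter classes append, never
# renumber, so existing draw streams are unaffected by model growth.
_CLASS_IDS = {"effect": 11, "survival_diagnosed": 12, "survival_none": 13}


@dataclass
class PSAConfig:
    """Settings for the Monte Carlo sensitivity analysis.

    ``families`` selects the sampling distribution per parameter class:
    truncated normal for the mortality effect (mean at the point
    estimate, sd such that the 80%/120% bounds are +/-1.96 sd, truncated
    at 0) and uniform for survival, both selectable.
    ``survival_rel_bounds`` are the relative bounds applied to the
    survival medians (the effect table carries its own bounds).
    """

    n_draws: int = 5000
    seed: int = 0
    percentiles: tuple[float, float] = (2.5, 97.5)
    families: dict[str, str] = field(
        default_factory=lambda: {"effect": "normal-truncated", "survival": "uniform"}
    )
    survival_rel_bounds: tuple[float, float] = (BOUND_LOW_FACTOR, BOUND_HIGH_FACTOR)

    def validate(self) -> "PSAConfig":
        if self.n_draws < 2:
            raise ValidationError("n_draws must be at least 2")
        lo, hi = self.percentiles
        if not (0 < lo < hi < 100):
            raise ValidationError("percentiles must be an ordered pair in (0, 100)")
        for cls, fam in self.families.items():
            if fam not in FAMILIES:
                raise SchemaError(f"unknown distribution family {fam!r} for {cls!r}")
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")
        return self


@dataclass
class ParameterDraw:
    """One realisation of the uncertain model parameters."""

    effect_draw: EffectTable
    survival_draw: SurvivalTable
    draw_id: int


def _effect_rel_bounds(effect: EffectTable) -> tuple[float, float]:
    """Relative (low, high) support of the shared effect factor,
    recovered from the table's bound columns."""
    df = effect.data
    pos = df["mrf_1pct"] > 0
    if not pos.any():
        return (1.0, 1.0)
    lo = float((df.loc[pos, "mrf_low"] / df.loc[pos, "mrf_1pct"]).median())
    hi = float((df.loc[pos, "mrf_high"] / df.loc[pos, "mrf_1pct"]).median())
    return (lo, hi)


def _draw_factor(
    seed: int, draw_id: int, param_class: str, family: str, lo: float, hi: float
) -> float:
    """Deterministic multiplicative factor for (seed, draw_id, class).

    The factor has point value 1 and support [lo, hi]; a zero-width
    support returns the point exactly.
    """
    if hi < lo:
        raise ValidationError(f"invalid bounds for {param_class!r}: {lo} > {hi}")
    if hi - lo <= 1e-15:
        return 1.0
    cid = _CLASS_IDS[param_class]
    rng = np.random.default_rng([seed, draw_id, cid])
    if family == "uniform":
        return float(rng.uniform(lo, hi))
    if family == "normal-truncated":
        sd = (hi - lo) / (2.0 * 1.96)
        a = (0.0 - 1.0) / sd  # truncate at 0
        return float(stats.truncnorm.rvs(a, np.inf, loc=1.0, scale=sd, random_state=rng))
    raise SchemaError(f"unknown distribution family {family!r}")


def _draw_factors(
    config: PSAConfig, effect: EffectTable, draw_id: int
) -> tuple[float, float, float]:
    e_lo, e_hi = _effect_rel_bounds(effect)
    s_lo, s_hi = config.survival_rel_bounds
    f_eff = _draw_factor(config.seed, draw_id, "effect", config.families["effect"], e_lo, e_hi)
    f_diag = _draw_factor(
        config.seed, draw_id, "survival_diagnosed", config.families["survival"], s_lo, s_hi
    )
    f_none = _draw_factor(
        config.seed, draw_id, "survival_none", config.families["survival"], s_lo, s_hi
    )
    return f_eff, f_diag, f_none


def draw_parameter_set(
    config: PSAConfig,
    effect: EffectTable,
    survival: SurvivalTable,
    draw_id: int,
) -> ParameterDraw:
    """Materialise one parameter draw as full effect/survival tables."""
    config.validate()
    f_eff, f_diag, f_none = _draw_factors(config, effect, draw_id)
    eff_point = f_eff * effect.data["mrf_1pct"]
    effect_draw = EffectTable(data=_with_bounds(eff_point))
    ms = survival.median_survival.copy()
    ms["diagnosed"] = f_diag * ms["diagnosed"]
    ms["none"] = f_none * ms["none"]
    ms["undiagnosed"] = 0.5 * (ms["diagnosed"] + ms["none"])
    survival_draw = SurvivalTable(median_survival=ms, le_index=survival.le_index.copy())
    return ParameterDraw(effect_draw=effect_draw, survival_draw=survival_draw, draw_id=draw_id)


def summarize_ci(draws, percentiles: tuple[float, float] = (2.5, 97.5)) -> tuple[float, float]:
    """Empirical (low, high) percentiles with linear interpolation
    between order statistics.  Asymmetry about the point estimate is
    expected for non-normal inputs."""
    arr = np.asarray(draws, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarise an empty draw vector")
    if not np.isfinite(arr).all():
        raise ValidationError("draw vector contains non-finite values")
    lo, hi = percentiles
    if not (0 < lo < hi < 100):
        raise ValidationError("percentiles must be an ordered pair in (0, 100)")
    low, high = np.percentile(arr, [lo, hi])
    return float(low), float(high)


@dataclass
class PSAResults:
    """Point estimates plus Monte Carlo confidence intervals.

    ``totals_ci`` maps each headline metric to (point, low, high);
    per-stratum CIs are frames with ``low``/``high`` columns aligned to
    the stratum index.  ``draw_totals`` keeps the per-draw totals for
    audit (one row per draw).
    """

    point: OutcomeResults
    dpp_ci: pd.DataFrame
    lyg_ci: pd.DataFrame
    admissions_ci: dict[str, pd.DataFrame]
    totals_ci: dict[str, tuple[float, float, float]]
    draw_totals: pd.DataFrame
    n_draws: int
    seed: int
    percentiles: tuple[float, float]


def run_psa(
    config: PSAConfig,
    baseline: BaselineScenario,
    admissions: AdmissionsBaseline,
    survival: SurvivalTable,
    effect: EffectTable,
    scenario: IntakeScenario,
    shares: SubgroupShares | None = None,
) -> PSAResults:
    """Monte Carlo propagation of parameter uncertainty.

    Point estimates come from the mean parameters; each draw rescales
    the effect and survival tables by the factors of
    :func:`draw_parameter_set` and re-runs the outcome computations.
    """
    config.validate()
    shares = shares or default_subgroup_shares()
    point = run_point(baseline, admissions, survival, effect, scenario, shares)

    idx = baseline.data.index
    deaths = baseline.data["expected_deaths"].to_numpy()
    adm = admissions.data[list(DISEASE_GROUPS)].reindex(idx).to_numpy()
    base_reduction = _stratum_mrf(idx, effect, scenario)

    # survival pieces, aligned to strata; the draw factors scale the
    # diagnosed / no-CHD medians and the midpoint rule is re-applied
    age = idx.get_level_values("age_band")
    q = idx.get_level_values("sec_quintile")
    surv_diag = survival.median_survival["diagnosed"].reindex(age).to_numpy()
    surv_none = survival.median_survival["none"].reindex(age).to_numpy()
    le = survival.le_index.reindex(q).to_numpy()
    sh = shares.validate().data.reindex(age)
    sh_d = sh["diagnosed"].to_numpy()
    sh_u = sh["undiagnosed"].to_numpy()
    sh_n = sh["none"].to_numpy()

    n = config.n_draws
    dpp_draws = np.empty((n, len(idx)))
    lyg_draws = np.empty((n, len(idx)))
    adm_draws = np.empty((n, len(idx), len(DISEASE_GROUPS)))
    for d in range(n):
        f_eff, f_diag, f_none = _draw_factors(config, effect, d)
        reduction = np.minimum(base_reduction * f_eff, 1.0)
        dpp_d = deaths * reduction
        sd = surv_diag * f_diag
        sn = surv_none * f_none
        eff_surv = sh_d * sd + sh_u * (0.5 * (sd + sn) * le) + sh_n * (sn * le)
        dpp_draws[d] = dpp_d
        lyg_draws[d] = dpp_d * eff_surv
        adm_draws[d] = adm * reduction[:, None]
        if not (
            np.isfinite(dpp_d).all() and np.isfinite(eff_surv).all()
        ):
            raise ValidationError(f"non-finite simulated value at draw_id={d}")

    pcts = list(config.percentiles)
    dpp_lo, dpp_hi = np.percentile(dpp_draws, pcts, axis=0)
    lyg_lo, lyg_hi = np.percentile(lyg_draws, pcts, axis=0)
    adm_lo, adm_hi = np.percentile(adm_draws, pcts, axis=0)

    dpp_ci = pd.DataFrame({"low": dpp_lo, "high": dpp_hi}, index=idx)
    lyg_ci = pd.DataFrame({"low": lyg_lo, "high": lyg_hi}, index=idx)
    admissions_ci = {
        g: pd.DataFrame({"low": adm_lo[:, j], "high": adm_hi[:, j]}, index=idx)
        for j, g in enumerate(DISEASE_GROUPS)
    }

    totals = point.totals()
    draw_totals = pd.DataFrame(
        {
            "dpp": dpp_draws.sum(axis=1),
            "lyg": lyg_draws.sum(axis=1),
            **{g: adm_draws[:, :, j].sum(axis=1) for j, g in enumerate(DISEASE_GROUPS)},
        }
    )
    draw_totals["admissions"] = draw_totals[list(DISEASE_GROUPS)].sum(axis=1)
    totals_ci = {}
    for metric, point_val in totals.items():
        low, high = summarize_ci(draw_totals[metric].to_numpy(), config.percentiles)
        totals_ci[metric] = (point_val, low, high)

    return PSAResults(
        point=point,
        dpp_ci=dpp_ci,
        lyg_ci=lyg_ci,
        admissions_ci=admissions_ci,
        totals_ci=totals_ci,
        draw_totals=draw_totals,
        n_draws=n,
        seed=config.seed,
        percentiles=tuple(config.percentiles),
    )
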