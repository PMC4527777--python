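"""Monte Carlo sensitivity analysis: determinism, percentiles, CIs."""

import numpy as np
import pandas as pd
import pytest

import impact_tfa as it
from impact_tfa.strata import ValidationError, SchemaError
from impact_tfa.uncertainty import _draw_factor, _draw_factors, summarize_ci

from conftest import make_effect_table


def degenerate_config(n_draws=50, seed=7):
    return it.PSAConfig(
        n_draws=n_draws, seed=seed, survival_rel_bounds=(1.0, 1.0)
    )


def degenerate_effect(values):
    table = make_effect_table(values)
    table.data["mrf_low"] = table.data["mrf_1pct"]
    table.data["mrf_high"] = table.data["mrf_1pct"]
    return table


def test_config_validation():
    with pytest.raises(ValidationError):
        it.PSAConfig(n_draws=1).validate()
    with pytest.raises(ValidationError):
        it.PSAConfig(percentiles=(97.5, 2.5)).validate()
    with pytest.raises(SchemaError):
        it.PSAConfig(families={"effect": "weibull", "survival": "uniform"}).validate()


def test_degenerate_support_returns_point_exactly(survival):
    cfg = degenerate_config()
    eff = degenerate_effect({"65-74": 0.1, "75-84": 0.08})
    draw = it.draw_parameter_set(cfg, eff, survival, draw_id=0)
    pd.testing.assert_series_equal(
        draw.effect_draw.data["mrf_1pct"], eff.data["mrf_1pct"]
    )
    pd.testing.assert_frame_equal(
        draw.survival_draw.median_survival, survival.median_survival
    )


def test_same_seed_and_draw_id_reproduce_the_draw(effect, survival):
    cfg = it.PSAConfig(n_draws=10, seed=42)
    d1 = it.draw_parameter_set(cfg, effect, survival, draw_id=3)
    d2 = it.draw_parameter_set(cfg, effect, survival, draw_id=3)
    pd.testing.assert_frame_equal(d1.effect_draw.data, d2.effect_draw.data)
    pd.testing.assert_frame_equal(
        d1.survival_draw.median_survival, d2.survival_draw.median_survival
    )


def test_draws_stay_inside_declared_support(effect, survival):
    cfg = it.PSAConfig(n_draws=10, seed=5,
                       families={"effect": "uniform", "survival": "uniform"})
    for d in range(50):
        draw = it.draw_parameter_set(cfg, effect, survival, d)
        point = effect.data["mrf_1pct"]
        assert (draw.effect_draw.data["mrf_1pct"] >= effect.data["mrf_low"] - 1e-12).all()
        assert (draw.effect_draw.data["mrf_1pct"] <= effect.data["mrf_high"] + 1e-12).all()
        assert (draw.survival_draw.median_survival >= 0).all().all()


def test_truncated_normal_draws_are_nonnegative(effect, survival):
    cfg = it.PSAConfig(n_draws=10, seed=5)
    factors = [_draw_factor(0, d, "effect", "normal-truncated", 0.8, 1.2)
               for d in range(2000)]
    assert min(factors) > 0


def test_uniform_factor_mean_matches_closed_form():
    """A factor drawn U(0.8, 1.2) applied to point 0.10 has mean 0.10:
    the sample mean over many draws must sit within 3 standard errors."""
    n = 8000
    draws = 0.10 * np.array(
        [_draw_factor(123, d, "effect", "uniform", 0.8, 1.2) for d in range(n)]
    )
    se = (0.12 - 0.08) / np.sqrt(12) / np.sqrt(n)
    assert abs(draws.mean() - 0.10) < 3 * se


@pytest.mark.parametrize(
    "percentiles, expected",
    [((2.5, 97.5), (3.475, 97.525)), ((5, 95), (5.95, 95.05))],
)
def test_percentiles_use_linear_interpolation(percentiles, expected):
    low, high = summarize_ci(np.arange(1, 101), percentiles)
    assert low == pytest.approx(expected[0])
    assert high == pytest.approx(expected[1])


def test_constant_draws_give_degenerate_ci():
    assert summarize_ci(np.full(10, 7.0)) == (7.0, 7.0)


def test_summarize_ci_rejects_empty_and_nonfinite():
    with pytest.raises(ValidationError):
        summarize_ci([])
    with pytest.raises(ValidationError):
        summarize_ci([1.0, np.nan])


def test_widening_percentiles_never_narrows_ci():
    rng = np.random.default_rng(0)
    draws = rng.normal(size=500)
    lo1, hi1 = summarize_ci(draws, (5, 95))
    lo2, hi2 = summarize_ci(draws, (2.5, 97.5))
    assert lo2 <= lo1 and hi2 >= hi1


def test_run_psa_degenerate_ci_equals_point(baseline, admissions, survival, shares):
    eff = degenerate_effect(
        {b: v for b, v in zip(it.AGE_BANDS, [0.2, 0.18, 0.15, 0.12, 0.1, 0.08, 0.06])}
    )
    sc = it.build_intake_scenario("equal", target_intake=0.3)
    psa = it.run_psa(degenerate_config(), baseline, admissions, survival, eff, sc, shares)
    for metric, (point, low, high) in psa.totals_ci.items():
        assert low == pytest.approx(point, abs=1e-9)
        assert high == pytest.approx(point, abs=1e-9)
    assert np.allclose(psa.dpp_ci["low"], psa.point.dpp)
    assert np.allclose(psa.lyg_ci["high"], psa.point.lyg)


def test_run_psa_is_seed_reproducible(baseline, admissions, survival, effect, shares):
    sc = it.build_intake_scenario("equal", target_intake=0.3)
    cfg = it.PSAConfig(n_draws=200, seed=11)
    r1 = it.run_psa(cfg, baseline, admissions, survival, effect, sc, shares)
    r2 = it.run_psa(cfg, baseline, admissions, survival, effect, sc, shares)
    pd.testing.assert_frame_equal(r1.dpp_ci, r2.dpp_ci)
    pd.testing.assert_frame_equal(r1.draw_totals, r2.draw_totals)
    assert r1.totals_ci == r2.totals_ci


def test_run_psa_ci_brackets_point(baseline, admissions, survival, effect, shares):
    sc = it.build_intake_scenario("equal", target_intake=0.3)
    cfg = it.PSAConfig(n_draws=400, seed=2)
    psa = it.run_psa(cfg, baseline, admissions, survival, effect, sc, shares)
    for metric, (point, low, high) in psa.totals_ci.items():
        assert low <= point <= high


def test_run_psa_matches_materialised_draws(baseline, admissions, survival,
                                            effect, shares):
    """The vectorised PSA path reproduces the outcome pipeline run on the
    materialised per-draw parameter tables."""
    sc = it.build_intake_scenario("equal", target_intake=0.3)
    cfg = it.PSAConfig(n_draws=5, seed=9,
                       families={"effect": "uniform", "survival": "uniform"})
    psa = it.run_psa(cfg, baseline, admissions, survival, effect, sc, shares)
    for d in range(cfg.n_draws):
        draw = it.draw_parameter_set(cfg, effect, survival, d)
        res = it.run_point(baseline, admissions, survival=draw.survival_draw,
                           effect=draw.effect_draw, scenario=sc, shares=shares)
        assert psa.draw_totals.loc[d, "dpp"] == pytest.approx(res.dpp.sum(), rel=1e-12)
        assert psa.draw_totals.loc[d, "lyg"] == pytest.approx(res.lyg.sum(), rel=1e-12)


def test_ci_width_shrinks_with_bounds(baseline, admissions, survival, effect, shares):
    sc = it.build_intake_scenario("equal", target_intake=0.3)
    cfg_wide = it.PSAConfig(n_draws=300, seed=4,
                            families={"effect": "uniform", "survival": "uniform"})
    cfg_narrow = it.PSAConfig(n_draws=300, seed=4,
                              families={"effect": "uniform", "survival": "uniform"},
                              survival_rel_bounds=(0.99, 1.01))
    narrow_eff = it.EffectTable(data=effect.data.assign(
        mrf_low=0.99 * effect.data["mrf_1pct"],
        mrf_high=1.01 * effect.data["mrf_1pct"],
    ))
    wide = it.run_psa(cfg_wide, baseline, admissions, survival, effect, sc, shares)
    narrow = it.run_psa(cfg_narrow, baseline, admissions, survival, narrow_eff,
                        sc, shares)
    for metric in ("dpp", "lyg"):
        _, wl, wh = wide.totals_ci[metric]
        _, nl, nh = narrow.totals_ci[metric]
        assert (nh - nl) < (wh - wl)
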