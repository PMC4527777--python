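"""Counterfactual outcome computations: hand oracles and invariants."""

import numpy as np
import pandas as pd
import pytest

import impact_tfa as it
from impact_tfa.outcomes import aggregate, compute_rate_index, round_display
from impact_tfa.strata import AGE_BANDS, QUINTILES, ValidationError

from conftest import make_effect_table, make_shares, make_survival, make_toy_baseline


def equal_unit_scenario():
    return it.build_intake_scenario("equal", target_intake=0.3)  # delta = 1.0


def test_dpp_is_deaths_times_reduction():
    baseline = make_toy_baseline([("65-74", "male", 3, 1000.0, 100000.0)])
    effect = make_effect_table({"65-74": 0.12})
    dpp = it.compute_dpp(baseline, effect, equal_unit_scenario())
    assert dpp.iloc[0] == pytest.approx(120.0)


def test_dpp_total_sums_strata():
    baseline = make_toy_baseline(
        [("55-64", "male", 2, 500.0, 1e5), ("65-74", "female", 4, 500.0, 1e5)]
    )
    effect = make_effect_table({"55-64": 0.1, "65-74": 0.2})
    dpp = it.compute_dpp(baseline, effect, equal_unit_scenario())
    assert dpp.sum() == pytest.approx(150.0)


def test_dpp_zero_delta_everywhere():
    baseline = make_toy_baseline([("65-74", "male", 3, 1000.0, 1e5)])
    effect = make_effect_table({"65-74": 0.12})
    null = it.build_intake_scenario("equal", target_intake=1.3)
    assert (it.compute_dpp(baseline, effect, null) == 0).all()


def test_dpp_missing_effect_row_is_an_error():
    baseline = make_toy_baseline([("25-34", "male", 1, 10.0, 1e4)])
    effect = make_effect_table({"65-74": 0.12})
    with pytest.raises(it.SchemaError, match="25-34"):
        it.compute_dpp(baseline, effect, equal_unit_scenario())


def test_lyg_midpoint_rule_all_undiagnosed():
    baseline = make_toy_baseline([("65-74", "male", 3, 100.0, 1e5)])
    effect = make_effect_table({"65-74": 0.1})
    dpp = it.compute_dpp(baseline, effect, equal_unit_scenario())  # 10 deaths
    survival = make_survival(diagnosed=4.0, none=8.0)
    shares = make_shares(diagnosed=0.0, undiagnosed=1.0, none=0.0)
    lyg = it.compute_lyg(dpp, survival, shares)
    assert lyg.iloc[0] == pytest.approx(60.0)  # 10 x midpoint(4, 8)


def test_lyg_le_index_scales_no_chd_survival():
    baseline = make_toy_baseline([("65-74", "male", 2, 100.0, 1e5)])
    effect = make_effect_table({"65-74": 0.1})
    dpp = it.compute_dpp(baseline, effect, equal_unit_scenario())
    le = {1: 1.1, 2: 1.2, 3: 1.0, 4: 0.9, 5: 0.8}
    survival = make_survival(diagnosed=4.0, none=10.0, le=le)
    shares = make_shares(diagnosed=0.0, undiagnosed=0.0, none=1.0)
    lyg = it.compute_lyg(dpp, survival, shares)
    assert lyg.iloc[0] == pytest.approx(120.0)  # 10 x 10y x 1.2


def test_lyg_diagnosed_survival_not_deprivation_indexed():
    """With all share on diagnosed CHD, lyg = dpp x diagnosed survival
    regardless of the quintile's life-expectancy index."""
    baseline = make_toy_baseline(
        [("65-74", "male", 1, 100.0, 1e5), ("65-74", "male", 5, 100.0, 1e5)]
    )
    effect = make_effect_table({"65-74": 0.1})
    dpp = it.compute_dpp(baseline, effect, equal_unit_scenario())
    le = {1: 1.2, 2: 1.1, 3: 1.0, 4: 0.9, 5: 0.8}
    survival = make_survival(diagnosed=6.0, none=12.0, le=le)
    shares = make_shares(diagnosed=1.0, undiagnosed=0.0, none=0.0)
    lyg = it.compute_lyg(dpp, survival, shares)
    assert np.allclose(lyg, dpp * 6.0)


def test_lyg_zero_dpp_gives_zero(survival, shares):
    baseline = make_toy_baseline([("65-74", "male", 3, 0.0, 1e5)])
    effect = make_effect_table({"65-74": 0.12})
    dpp = it.compute_dpp(baseline, effect, equal_unit_scenario())
    assert (it.compute_lyg(dpp, survival, shares) == 0).all()


def test_shares_must_sum_to_one():
    with pytest.raises(ValidationError, match="sum to 1"):
        make_shares(diagnosed=0.5, undiagnosed=0.5, none=0.5).validate()


def test_admissions_preserve_group_ratios(effect):
    idx = pd.MultiIndex.from_tuples(
        [("65-74", "male", 3)], names=["age_band", "sex", "sec_quintile"]
    )
    adm = it.AdmissionsBaseline(
        data=pd.DataFrame({"AMI": [1000.0], "UA": [4000.0], "HF": [1000.0]}, index=idx)
    )
    avoided = it.compute_admissions_avoided(adm, effect, equal_unit_scenario())
    row = avoided.iloc[0]
    assert row["UA"] / row["AMI"] == pytest.approx(4.0)
    assert row["HF"] / row["AMI"] == pytest.approx(1.0)


def test_admissions_hand_product():
    idx = pd.MultiIndex.from_tuples(
        [("65-74", "male", 3)], names=["age_band", "sex", "sec_quintile"]
    )
    adm = it.AdmissionsBaseline(
        data=pd.DataFrame({"AMI": [1000.0], "UA": [0.0], "HF": [0.0]}, index=idx)
    )
    effect = make_effect_table({"65-74": 0.1})
    avoided = it.compute_admissions_avoided(adm, effect, equal_unit_scenario())
    assert avoided.iloc[0]["AMI"] == pytest.approx(100.0)


def test_aggregates_conserve_totals(baseline, admissions, survival, effect, shares):
    res = it.run_point(baseline, admissions, survival, effect,
                       equal_unit_scenario(), shares)
    frame = res.frame()
    grand = frame.sum()
    for by in (["sex"], ["sec_quintile"], ["sex", "coarse_band"],
               ["coarse_band", "sex", "sec_quintile"]):
        agg = aggregate(frame, by)
        assert np.allclose(agg.sum(), grand, rtol=1e-9)


def test_coarse_band_totals_sum_members(baseline, effect):
    dpp = it.compute_dpp(baseline, effect, equal_unit_scenario())
    agg = aggregate(dpp, ["coarse_band"])
    young = dpp[dpp.index.get_level_values("age_band").isin(AGE_BANDS[:3])].sum()
    assert agg.loc["<55"] == pytest.approx(young, rel=1e-12)


def test_incomplete_age_grouping_rejected(baseline, effect):
    dpp = it.compute_dpp(baseline, effect, equal_unit_scenario())
    bad = it.AgeGrouping(mapping={"25-34": "<55"})
    with pytest.raises(ValidationError, match="cover"):
        aggregate(dpp, ["coarse_band"], grouping=bad)


def test_rate_index_anchored_at_quintile_three(baseline, effect):
    dpp = it.compute_dpp(baseline, effect, equal_unit_scenario())
    ri = compute_rate_index(dpp, baseline.data["population"])
    assert ri.loc[3, "index"] == 1.0
    grouped = compute_rate_index(dpp, baseline.data["population"], by=["sex"])
    anchors = grouped.xs(3, level="sec_quintile")["index"]
    assert (anchors == 1.0).all()


def test_rate_index_ratio_definition():
    rows = [("65-74", "male", q, 10.0 * (2.0 if q == 5 else 1.0), 1000.0)
            for q in QUINTILES]
    baseline = make_toy_baseline(rows)
    effect = make_effect_table({"65-74": 0.1})
    dpp = it.compute_dpp(baseline, effect, equal_unit_scenario())
    ri = compute_rate_index(dpp, baseline.data["population"])
    assert ri.loc[5, "index"] == pytest.approx(2.0)
    assert ri.loc[1, "index"] == pytest.approx(1.0)


def test_rate_index_zero_anchor_is_error():
    rows = [("65-74", "male", q, 0.0, 1000.0) for q in QUINTILES]
    baseline = make_toy_baseline(rows)
    effect = make_effect_table({"65-74": 0.1})
    dpp = it.compute_dpp(baseline, effect, equal_unit_scenario())
    with pytest.raises(ValidationError, match="undefined"):
        compute_rate_index(dpp, baseline.data["population"])


@pytest.mark.parametrize(
    "value, expected",
    [(3871, 3900.0), (37123, 37000.0), (86, 100.0), (9850, 9800.0), (0, 0.0)],
)
def test_display_rounding_rule(value, expected):
    assert round_display(value) == expected
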