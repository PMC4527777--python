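import numpy as np
import pandas as pd
import pytest

import impact_tfa as it
from impact_tfa.strata import AGE_BANDS, QUINTILES, SEXES


@pytest.fixture(scope="session")
def spec():
    return it.SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def baseline(spec):
    return it.generate_baseline(spec)


@pytest.fixture(scope="session")
def admissions(spec, baseline):
    return it.generate_admissions(spec, baseline)


@pytest.fixture(scope="session")
def survival(spec):
    return it.generate_survival(spec)


@pytest.fixture(scope="session")
def effect(baseline):
    return it.build_effect_table(population_weights=it.population_weights(baseline))


@pytest.fixture(scope="session")
def shares():
    return it.default_subgroup_shares()


def make_effect_table(values_by_age, sexes=SEXES):
    """EffectTable from an age->mrf mapping, same value for both sexes."""
    idx = pd.MultiIndex.from_product(
        [list(values_by_age), list(sexes)], names=["age_band", "sex"]
    )
    point = pd.Series(
        [values_by_age[a] for a, _ in idx], index=idx, dtype=float
    )
    return it.EffectTable(
        data=pd.DataFrame(
            {"mrf_1pct": point, "mrf_low": 0.8 * point, "mrf_high": 1.2 * point}
        )
    )


def make_toy_baseline(rows):
    """BaselineScenario from (age_band, sex, quintile, deaths, population) rows.

    Bypasses the 70-stratum completeness check: engine computations are
    defined on any consistent subset of strata.
    """
    idx = pd.MultiIndex.from_tuples(
        [r[:3] for r in rows], names=["age_band", "sex", "sec_quintile"]
    )
    data = pd.DataFrame(
        {"expected_deaths": [r[3] for r in rows], "population": [r[4] for r in rows]},
        index=idx,
    )
    return it.BaselineScenario(data=data)


def make_survival(diagnosed, none, le=None):
    """SurvivalTable with constant medians across age bands."""
    ms = pd.DataFrame(
        {
            "diagnosed": diagnosed,
            "undiagnosed": 0.5 * (diagnosed + none),
            "none": none,
        },
        index=pd.Index(AGE_BANDS, name="age_band"),
    )
    le_s = pd.Series(
        le if le is not None else {q: 1.0 for q in QUINTILES}, name="le_index"
    )
    le_s.index.name = "sec_quintile"
    return it.SurvivalTable(median_survival=ms, le_index=le_s)


def make_shares(diagnosed, undiagnosed, none):
    df = pd.DataFrame(
        {"diagnosed": diagnosed, "undiagnosed": undiagnosed, "none": none},
        index=pd.Index(AGE_BANDS, name="age_band"),
        dtype=float,
    )
    return it.SubgroupShares(data=df)
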