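"""Stratified tables for the coronary heart disease policy model.

Everything the model reads or writes is keyed by a 70-cell
stratification of the adult England-and-Wales-like population:
seven ten-year age bands (25-34 up to 85+), two sexes, and five
socio-economic quintiles derived from area deprivation scores.

Orientation convention (fixed throughout the package, configurable only
at data-preparation time): quintile 1 is the most affluent, quintile 5
the most deprived.  Age bands are written with an ASCII hyphen in files
("25-34" ... "85+").  Counts are stored as non-negative reals, since
expected deaths from a forecast need not be integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AGE_BANDS: tuple[str, ...] = ("25-34", "35-44", "45-54", "55-64", "65-74", "75-84", "85+")
SEXES: tuple[str, ...] = ("male", "female")
QUINTILES: tuple[int, ...] = (1, 2, 3, 4, 5)

#: Incident disease groups in scope: acute myocardial infarction,
#: unstable angina, heart failure admissions.  Community-prevalence
#: groups (chronic angina, community heart failure, MI survivors) are
#: deliberately excluded: the policy is assumed to have negligible
#: effect on case fatality, hence on community prevalence.
DISEASE_GROUPS: tuple[str, ...] = ("AMI", "UA", "HF")

CHD_STATES: tuple[str, ...] = ("diagnosed", "undiagnosed", "none")

COARSE_BANDS: tuple[str, ...] = ("<55", "55-74", ">=75")

STRATUM_LEVELS: tuple[str, ...] = ("age_band", "sex", "sec_quintile")


class SchemaError(ValueError):
    """A file or table does not have the expected shape/columns/keys."""


class ValidationError(ValueError):
    """A table is well-formed but violates a model invariant."""


def stratum_index() -> pd.MultiIndex:
    """The canonical 70-row (age_band, sex, sec_quintile) index."""
    return pd.MultiIndex.from_product(
        [AGE_BANDS, SEXES, QUINTILES], names=list(STRATUM_LEVELS)
    )


def stratum_label(key: tuple) -> str:
    return "(" + ", ".join(str(k) for k in key) + ")"


@dataclass(frozen=True)
class AgeGrouping:
    """Mapping of fine ten-year age bands onto coarse analysis bands.

    The default groups under-55s, the 55-74 middle band and 75+
    (inclusive boundaries on the fine bands).
    """

    mapping: dict[str, str] = field(
        default_factory=lambda: {
            "25-34": "<55",
            "35-44": "<55",
            "45-54": "<55",
            "55-64": "55-74",
            "65-74": "55-74",
            "75-84": ">=75",
            "85+": ">=75",
        }
    )

    def validate(self) -> "AgeGrouping":
        missing = [b for b in AGE_BANDS if b not in self.mapping]
        if missing:
            raise ValidationError(f"age grouping does not cover fine bands: {missing}")
        return self

    def coarse(self, age_bands) -> np.ndarray:
        self.validate()
        return np.asarray([self.mapping[b] for b in age_bands])


DEFAULT_AGE_GROUPING = AgeGrouping()


def _check_stratum_frame(df: pd.DataFrame, context: str) -> None:
    """Check a stratum-indexed frame covers all 70 strata exactly once."""
    idx = df.index
    if idx.names != list(STRATUM_LEVELS):
        raise SchemaError(f"{context}: index levels must be {STRATUM_LEVELS}, got {idx.names}")
    dup = idx[idx.duplicated()]
    if len(dup):
        raise SchemaError(f"{context}: duplicate stratum {stratum_label(dup[0])}")
    full = stratum_index()
    missing = full.difference(idx)
    if len(missing):
        raise SchemaError(f"{context}: missing stratum {stratum_label(missing[0])}")
    extra = idx.difference(full)
    if len(extra):
        raise SchemaError(f"{context}: unknown stratum {stratum_label(extra[0])}")


def _check_nonnegative(df: pd.DataFrame, columns, context: str) -> None:
    for col in columns:
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValidationError(
                f"{context}: negative {col} in stratum {stratum_label(bad[0])}"
            )
        if df[col].isna().any():
            bad = df.index[df[col].isna()]
            raise ValidationError(
                f"{context}: missing {col} in stratum {stratum_label(bad[0])}"
            )


@dataclass
class BaselineScenario:
    """Expected CHD deaths and population per stratum for one scenario year.

    ``data`` is indexed by (age_band, sex, sec_quintile) with columns
    ``expected_deaths`` (CHD deaths/year the forecast expects with no
    intake change) and ``population`` (adults alive in the stratum).
    """

    data: pd.DataFrame
    year_label: str = ""

    def validate(self) -> "BaselineScenario":
        _check_stratum_frame(self.data, "baseline")
        for col in ("expected_deaths", "population"):
            if col not in self.data.columns:
                raise SchemaError(f"baseline: missing column {col!r}")
        _check_nonnegative(self.data, ("expected_deaths", "population"), "baseline")
        bad = self.data.index[self.data["population"] <= 0]
        if len(bad):
            raise ValidationError(
                f"baseline: non-positive population in stratum {stratum_label(bad[0])}"
            )
        bad = self.data.index[self.data["expected_deaths"] > self.data["population"]]
        if len(bad):
            raise ValidationError(
                f"baseline: expected_deaths exceeds population in stratum {stratum_label(bad[0])}"
            )
        return self


@dataclass
class AdmissionsBaseline:
    """Incident hospital admissions per stratum and disease group.

    ``data`` is indexed by stratum with one column per incident disease
    group (AMI, UA, HF).  Community-prevalence groups are rejected at
    read time: only incidence enters the admissions counterfactual.
    """

    data: pd.DataFrame

    def validate(self) -> "AdmissionsBaseline":
        _check_stratum_frame(self.data, "admissions")
        unknown = [c for c in self.data.columns if c not in DISEASE_GROUPS]
        if unknown:
            raise SchemaError(
                f"admissions: unknown disease group {unknown[0]!r}; only incident "
                f"groups {DISEASE_GROUPS} are modelled (community-prevalence "
                "groups are out of scope)"
            )
        missing = [g for g in DISEASE_GROUPS if g not in self.data.columns]
        if missing:
            raise SchemaError(f"admissions: missing disease group {missing[0]!r}")
        _check_nonnegative(self.data, DISEASE_GROUPS, "admissions")
        return self


@dataclass
class SurvivalTable:
    """Median survival by age band and CHD state, plus SEC life-expectancy indices.

    ``median_survival`` is indexed by age_band with columns
    ``diagnosed``, ``undiagnosed``, ``none`` (years).  The undiagnosed
    column is the midpoint of the other two by convention; if absent it
    is filled at validation time.  ``le_index`` maps quintile -> a
    dimensionless life-expectancy ratio anchored at exactly 1.0 for
    quintile 3; it scales survival in the undiagnosed/no-CHD states
    (diagnosed-CHD survival is not deprivation-stratified).
    """

    median_survival: pd.DataFrame
    le_index: pd.Series

    def validate(self) -> "SurvivalTable":
        ms = self.median_survival
        if list(ms.index.names) not in (["age_band"], [None]):
            raise SchemaError("survival: index must be age_band")
        missing_bands = [b for b in AGE_BANDS if b not in ms.index]
        if missing_bands:
            raise SchemaError(f"survival: missing age band {missing_bands[0]!r}")
        for state in ("diagnosed", "none"):
            if state not in ms.columns:
                raise SchemaError(f"survival: missing chd_state column {state!r}")
        ms = ms.reindex(AGE_BANDS)
        if "undiagnosed" not in ms.columns or ms["undiagnosed"].isna().all():
            ms["undiagnosed"] = 0.5 * (ms["diagnosed"] + ms["none"])
        if (ms[list(CHD_STATES)] <= 0).any().any():
            raise ValidationError("survival: median survival must be positive")
        for state in CHD_STATES:
            vals = ms[state].to_numpy()
            if np.any(np.diff(vals) > 1e-12):
                raise ValidationError(
                    f"survival: median survival for state {state!r} must be "
                    "non-increasing with age"
                )
        bad = ms.index[ms["diagnosed"] > ms["none"]]
        if len(bad):
            raise ValidationError(
                f"survival: diagnosed survival exceeds no-CHD survival at age {bad[0]!r}"
            )
        bad = ms.index[
            (ms["undiagnosed"] > ms["none"]) | (ms["undiagnosed"] < ms["diagnosed"])
        ]
        if len(bad):
            raise ValidationError(
                f"survival: undiagnosed survival outside [diagnosed, none] at age {bad[0]!r}"
            )
        self.median_survival = ms

        le = self.le_index
        missing_q = [q for q in QUINTILES if q not in le.index]
        if missing_q:
            raise SchemaError(f"survival: le_index missing quintile {missing_q[0]}")
        le = le.reindex(list(QUINTILES)).astype(float)
        if (le <= 0).any():
            raise ValidationError("survival: le_index must be positive")
        if abs(le.loc[3] - 1.0) > 1e-9:
            raise ValidationError(
                f"survival: le_index must equal 1.0 at quintile 3 (the anchor), got {le.loc[3]}"
            )
        self.le_index = le
        return self


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _read_csv(path, context: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{context}: file {path} is empty") from None
    if df.empty:
        raise SchemaError(f"{context}: file {path} has no data rows")
    return df


def _require_columns(df: pd.DataFrame, cols, context: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{context}: missing column {missing[0]!r}")


def _to_stratum_index(df: pd.DataFrame, context: str) -> pd.DataFrame:
    df = df.copy()
    try:
        df["sec_quintile"] = df["sec_quintile"].astype(int)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{context}: sec_quintile must be integer 1..5") from exc
    df["age_band"] = df["age_band"].astype(str).str.strip()
    df["sex"] = df["sex"].astype(str).str.strip().str.lower()
    return df.set_index(list(STRATUM_LEVELS))


def read_baseline(path, year_label: str = "") -> BaselineScenario:
    """Read and validate a baseline scenario CSV.

    Expected columns: age_band, sex, sec_quintile, expected_deaths, population.
    """
    df = _read_csv(path, "baseline")
    _require_columns(
        df, list(STRATUM_LEVELS) + ["expected_deaths", "population"], "baseline"
    )
    df = _to_stratum_index(df, "baseline")
    return BaselineScenario(
        data=df[["expected_deaths", "population"]].astype(float),
        year_label=year_label,
    ).validate()


def write_baseline(baseline: BaselineScenario, path) -> None:
    baseline.data[["expected_deaths", "population"]].reset_index().to_csv(path, index=False)


def read_admissions(path) -> AdmissionsBaseline:
    """Read incident admissions (long CSV: stratum, disease_group, admissions)."""
    df = _read_csv(path, "admissions")
    _require_columns(
        df, list(STRATUM_LEVELS) + ["disease_group", "admissions"], "admissions"
    )
    unknown = sorted(set(df["disease_group"]) - set(DISEASE_GROUPS))
    if unknown:
        raise SchemaError(
            f"admissions: unknown disease group {unknown[0]!r}; only incident "
            f"groups {DISEASE_GROUPS} are modelled (community-prevalence groups "
            "such as chronic angina are out of scope)"
        )
    df = _to_stratum_index(df, "admissions")
    dup = df.set_index("disease_group", append=True).index
    if dup.duplicated().any():
        key = dup[dup.duplicated()][0]
        raise SchemaError(f"admissions: duplicate row for {stratum_label(key)}")
    wide = (
        df.set_index("disease_group", append=True)["admissions"].astype(float).unstack()
    )
    wide.columns.name = None
    if wide.isna().any().any():
        r, c = np.argwhere(wide.isna().to_numpy())[0]
        raise SchemaError(
            f"admissions: missing row for stratum {stratum_label(wide.index[r])} "
            f"group {wide.columns[c]!r}"
        )
    return AdmissionsBaseline(data=wide[list(DISEASE_GROUPS)]).validate()


def write_admissions(adm: AdmissionsBaseline, path) -> None:
    long = (
        adm.data.stack()
        .rename("admissions")
        .rename_axis(list(STRATUM_LEVELS) + ["disease_group"])
        .reset_index()
    )
    long.to_csv(path, index=False)


def read_survival(survival_path, le_index_path) -> SurvivalTable:
    """Read median-survival (age_band, chd_state, median_survival) and the
    quintile life-expectancy index block (sec_quintile, le_index)."""
    df = _read_csv(survival_path, "survival")
    _require_columns(df, ["age_band", "chd_state", "median_survival"], "survival")
    unknown = sorted(set(df["chd_state"]) - set(CHD_STATES))
    if unknown:
        raise SchemaError(f"survival: unknown chd_state {unknown[0]!r}")
    wide = (
        df.assign(age_band=df["age_band"].astype(str).str.strip())
        .set_index(["age_band", "chd_state"])["median_survival"]
        .astype(float)
        .unstack()
    )
    wide.columns.name = None
    wide.index.name = "age_band"

    le_df = _read_csv(le_index_path, "survival")
    _require_columns(le_df, ["sec_quintile", "le_index"], "survival")
    le = le_df.set_index(le_df["sec_quintile"].astype(int))["le_index"].astype(float)
    return SurvivalTable(median_survival=wide, le_index=le).validate()


def write_survival(surv: SurvivalTable, survival_path, le_index_path) -> None:
    long = (
        surv.median_survival[list(CHD_STATES)]
        .stack()
        .rename("median_survival")
        .rename_axis(["age_band", "chd_state"])
        .reset_index()
    )
    long.to_csv(survival_path, index=False)
    le = surv.le_index.rename("le_index").rename_axis("sec_quintile").reset_index()
    le.to_csv(le_index_path, index=False)
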