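"""Indirect age-standardization: expected counts and standardized incidence ratios.

The registry surrogate is a long table with one row per (area, age group):
observed case counts and person-years at risk. Reference age-specific rates
are pooled internally over the whole study region by default (so the region
plays the role of the "province"); external rates can be supplied instead.
Expected counts follow the indirect method, E_i = sum_a PY_{i,a} * r_a, and
the standardized incidence ratio is SIR_i = O_i / E_i.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_AGE_GROUPS",
    "default_age_groups",
    "validate_stratified",
    "pooled_reference_rates",
    "expected_counts",
    "compute_sir",
    "area_summary",
]


def default_age_groups() -> list[str]:
    """The 19 five-year age groups 0-4, 5-9, ..., 85-89, 90+."""
    groups = [f"{5 * k}-{5 * k + 4}" for k in range(18)]
    groups.append("90+")
    return groups


DEFAULT_AGE_GROUPS = default_age_groups()

_COLS = ["area_id", "age_group", "cases", "person_years"]


def validate_stratified(data: pd.DataFrame) -> pd.DataFrame:
    """Check the stratified count table and return a normalized copy.

    Enforces: required columns present; no duplicated (area, age group) cell;
    non-negative counts and person-years; no cases in strata with zero
    person-years.
    """
    missing = [c for c in _COLS if c not in data.columns]
    if missing:
        raise ValueError(f"stratified data missing columns: {missing}")
    df = data.loc[:, _COLS].copy()
    df["area_id"] = df["area_id"].astype(str)
    df["age_group"] = df["age_group"].astype(str)
    df["cases"] = pd.to_numeric(df["cases"])
    df["person_years"] = pd.to_numeric(df["person_years"])
    dup = df.duplicated(["area_id", "age_group"])
    if dup.any():
        keys = df.loc[dup, ["area_id", "age_group"]].values.tolist()
        raise ValueError(f"duplicated (area, age_group) cells: {keys[:5]}")
    if (df["cases"] < 0).any() or (df["person_years"] < 0).any():
        raise ValueError("negative cases or person_years")
    bad = (df["person_years"] == 0) & (df["cases"] > 0)
    if bad.any():
        raise ValueError(
            "cases observed in strata with zero person-years: "
            f"{df.loc[bad, ['area_id', 'age_group']].values.tolist()[:5]}"
        )
    return df


def pooled_reference_rates(data: pd.DataFrame) -> pd.Series:
    """Age-specific reference rates pooled over all areas.

    r_a = (sum_i cases_{i,a}) / (sum_i person_years_{i,a}); a stratum with
    zero person-years everywhere (and hence zero cases) gets rate 0. A
    stratum with cases but no person-years is an error.
    """
    df = validate_stratified(data)
    g = df.groupby("age_group", sort=False)[["cases", "person_years"]].sum()
    zero_py = g["person_years"] == 0
    if (zero_py & (g["cases"] > 0)).any():
        bad = g.index[zero_py & (g["cases"] > 0)].tolist()
        raise ValueError(f"strata with cases but zero person-years: {bad}")
    rates = np.where(zero_py, 0.0, g["cases"] / g["person_years"].where(~zero_py, 1.0))
    return pd.Series(rates, index=g.index, name="rate")


def expected_counts(data: pd.DataFrame, rates: pd.Series) -> pd.Series:
    """Indirectly standardized expected count per area, E_i = sum_a PY_{i,a} r_a."""
    df = validate_stratified(data)
    present = set(df["age_group"])
    missing = present - set(rates.index)
    if missing:
        raise ValueError(f"no reference rate for strata: {sorted(missing)}")
    df = df.assign(expected=df["person_years"] * df["age_group"].map(rates).to_numpy())
    e = df.groupby("area_id", sort=False)["expected"].sum()
    e.name = "expected"
    return e


def compute_sir(observed: pd.Series, expected: pd.Series) -> pd.DataFrame:
    """Per-area observed, expected and SIR = O/E.

    SIR is NaN (reported as missing) where E = 0; negative inputs are an
    error. Rounding happens only at report time.
    """
    observed = pd.Series(observed).astype(float)
    expected = pd.Series(expected).astype(float)
    if (observed < 0).any() or (expected < 0).any():
        raise ValueError("negative observed or expected counts")
    expected = expected.reindex(observed.index)
    if expected.isna().any():
        raise ValueError("expected counts missing for some areas")
    sir = observed / expected.where(expected > 0, np.nan)
    return pd.DataFrame(
        {"observed": observed, "expected": expected, "sir": sir}
    ).rename_axis("area_id")


def area_summary(
    data: pd.DataFrame, rates: pd.Series | None = None
) -> pd.DataFrame:
    """Full indirect-standardization pass: O, E and SIR per area.

    With ``rates=None`` the reference rates are pooled internally from the
    data, in which case sum(E) = sum(O) exactly (conservation) and the pooled
    SIR is 1.
    """
    df = validate_stratified(data)
    if rates is None:
        rates = pooled_reference_rates(df)
    obs = df.groupby("area_id", sort=False)["cases"].sum().astype(float)
    exp = expected_counts(df, rates)
    return compute_sir(obs, exp.reindex(obs.index))
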