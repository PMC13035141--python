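"""Regressor design shared by the first-stage equations and the generator.

Both first-stage regressions use the same household covariate block Z:
log household size and its square, the age-sex composition shares (baseline
females over 49 dropped), head sex, log head education and its square,
male-member count, log maximum education and its square, consumption
quintile dummies (first quintile baseline) and an urban indicator — plus
log total expenditure and survey-year dummies (first wave baseline).

Education enters as log(1 + years) so zero-schooling households stay in
the sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LN_X = "ln_total_expenditure"


def covariate_names(df: pd.DataFrame) -> list[str]:
    years = sorted(df["year"].unique())
    quintiles = sorted(df["quintile"].unique())
    names = [
        "ln_hh_size",
        "ln_hh_size_sq",
        "share_m_0_5",
        "share_f_0_5",
        "share_m_6_17",
        "share_f_6_17",
        "share_m_18_49",
        "share_f_18_49",
        "share_m_gt49",
        "head_female",
        "ln_head_educ",
        "ln_head_educ_sq",
        "n_male",
        "ln_max_educ",
        "ln_max_educ_sq",
    ]
    names += [f"quintile_{q}" for q in quintiles[1:]]
    names += ["urban"]
    names += [f"year_{y}" for y in years[1:]]
    return names


def build_design(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Return the (n, k) regressor matrix [ln x | Z | year dummies].

    Requires a preprocessed frame (``quintile`` present).  No intercept
    column: the fixed-effect absorption (or an explicit constant added by
    the caller) handles the level.
    """
    n = len(df)
    cols: dict[str, np.ndarray] = {}
    cols[LN_X] = np.log(df["total_expenditure"].to_numpy(float))
    ln_hh = np.log(df["hh_size"].to_numpy(float))
    cols["ln_hh_size"] = ln_hh
    cols["ln_hh_size_sq"] = ln_hh**2
    for c in [
        "share_m_0_5", "share_f_0_5", "share_m_6_17", "share_f_6_17",
        "share_m_18_49", "share_f_18_49", "share_m_gt49",
    ]:
        cols[c] = df[c].to_numpy(float)
    cols["head_female"] = df["head_female"].to_numpy(float)
    ln_he = np.log1p(df["head_educ_years"].to_numpy(float))
    cols["ln_head_educ"] = ln_he
    cols["ln_head_educ_sq"] = ln_he**2
    cols["n_male"] = df["n_male"].to_numpy(float)
    ln_me = np.log1p(df["max_educ_years"].to_numpy(float))
    cols["ln_max_educ"] = ln_me
    cols["ln_max_educ_sq"] = ln_me**2
    for q in sorted(df["quintile"].unique())[1:]:
        cols[f"quintile_{q}"] = (df["quintile"].to_numpy() == q).astype(float)
    cols["urban"] = df["urban"].to_numpy(float)
    for y in sorted(df["year"].unique())[1:]:
        cols[f"year_{y}"] = (df["year"].to_numpy() == y).astype(float)

    names = [LN_X] + covariate_names(df)
    X = np.column_stack([cols[name] for name in names])
    assert X.shape == (n, len(names))
    return X, names


def year_effect_names(names: list[str]) -> list[str]:
    return [c for c in names if c.startswith("year_")]
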