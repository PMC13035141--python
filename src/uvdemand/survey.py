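"""Household-by-wave survey records: loading, validation and preprocessing.

The in-memory container is a :class:`pandas.DataFrame` with one row per
household x wave and the canonical columns of
:data:`uvdemand.config.CANONICAL_COLUMNS`, plus derived columns added by
:func:`preprocess`:

``unit_value``
    cigarette expenditure / quantity (currency per stick), NaN for
    non-consuming records — never stored as zero;
``budget_share``
    cigarette expenditure / total consumption expenditure;
``quintile``
    consumption quintile (1..5) from pooled per-capita total expenditure.

All currency values are weekly amounts in base-year prices after
preprocessing; ``DataFrame.attrs`` carries a ``deflated_to`` flag so that
deflation is idempotent.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import (
    CANONICAL_COLUMNS,
    CURRENCY_COLUMNS,
    SHARE_COLUMNS,
    PipelineConfig,
)
from .errors import ConfigurationError, DataInconsistencyError, ValidationError

_NONNEGATIVE = ["cig_expenditure", "cig_quantity", "weight"]


# ---------------------------------------------------------------------------
# loading & validation
# ---------------------------------------------------------------------------

def load_survey(path, config: Optional[PipelineConfig] = None) -> pd.DataFrame:
    """Read a delimited text file of household-wave records.

    The delimiter is sniffed from the extension (``.tsv`` -> tab, else
    comma).  Source columns are renamed through ``config.column_map``;
    missing canonical columns raise :class:`ConfigurationError`.  Rows with
    missing total expenditure are dropped and their household ids reported
    on the returned frame's ``attrs['dropped_missing_total']``.
    """
    config = config or PipelineConfig()
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if config.column_map:
        df = df.rename(columns=config.column_map)

    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"input file {path} lacks required columns {missing}; "
            "map source names via config.column_map"
        )

    # reject rows with missing total expenditure, reporting ids
    bad_total = df["total_expenditure"].isna()
    dropped = df.loc[bad_total, "household_id"].tolist()
    if dropped:
        df = df.loc[~bad_total].copy()
    df.attrs["dropped_missing_total"] = dropped

    validate_records(df)
    return df.reset_index(drop=True)


def validate_records(df: pd.DataFrame) -> None:
    """Check the record-level data contract, naming offending rows."""
    for col in _NONNEGATIVE:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() | (values < 0)].tolist()
        if bad:
            raise ValidationError(
                f"column {col!r} must be numeric and >= 0; offending rows: {bad[:20]}"
            )
    total = pd.to_numeric(df["total_expenditure"], errors="coerce")
    bad = df.index[total.isna() | (total <= 0)].tolist()
    if bad:
        raise ValidationError(
            f"total_expenditure must be numeric and > 0; offending rows: {bad[:20]}"
        )
    share_sum = df[SHARE_COLUMNS].sum(axis=1)
    bad = df.index[(share_sum - 1.0).abs() > 1e-6].tolist()
    if bad:
        raise ValidationError(
            f"age-sex composition shares must sum to 1; offending rows: {bad[:20]}"
        )
    # positive spending with zero quantity is unrecoverable
    incons = df.index[(df["cig_expenditure"] > 0) & (df["cig_quantity"] <= 0)].tolist()
    if incons:
        raise DataInconsistencyError(
            "positive cigarette expenditure with zero quantity; "
            f"offending rows: {incons[:20]}"
        )


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------

def to_weekly(annual_value, recall_divisor: float):
    """Convert an annual recall amount to its weekly equivalent."""
    return np.asarray(annual_value, dtype=float) / recall_divisor if np.ndim(annual_value) else float(annual_value) / recall_divisor


def compute_unit_value(cig_expenditure, cig_quantity):
    """Unit value = expenditure / quantity; NaN where both are zero.

    Positive expenditure with zero quantity raises
    :class:`DataInconsistencyError` (there is no price that rationalises
    it).
    """
    e = np.asarray(cig_expenditure, dtype=float)
    q = np.asarray(cig_quantity, dtype=float)
    scalar = e.ndim == 0
    e, q = np.atleast_1d(e), np.atleast_1d(q)
    bad = (q <= 0) & (e > 0)
    if bad.any():
        raise DataInconsistencyError(
            f"expenditure > 0 with quantity == 0 at positions {np.flatnonzero(bad)[:20].tolist()}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(q > 0, e / q, np.nan)
    return float(v[0]) if scalar else v


def deflate(df: pd.DataFrame, cpi_series: dict, base_year: int) -> pd.DataFrame:
    """Express all currency columns in base-year prices.

    ``value_out = value_in * cpi(base_year) / cpi(year)``.  Idempotent: a
    frame whose ``attrs['deflated_to']`` already equals ``base_year`` is
    returned unchanged.
    """
    if df.attrs.get("deflated_to") == base_year:
        return df
    if base_year not in cpi_series:
        raise ConfigurationError(f"cpi_series lacks base year {base_year}")
    years = df["year"].unique()
    missing = [y for y in years if y not in cpi_series]
    if missing:
        raise ConfigurationError(f"cpi_series lacks survey years {missing}")
    out = df.copy()
    factor = df["year"].map({y: cpi_series[base_year] / cpi_series[y] for y in years})
    for col in CURRENCY_COLUMNS:
        if col in out.columns:
            out[col] = out[col] * factor
    out.attrs = dict(df.attrs)
    out.attrs["deflated_to"] = base_year
    return out


def assign_quintiles(df: pd.DataFrame, n_quantiles: int = 5) -> pd.Series:
    """Consumption quantile (1..n) from pooled per-capita total expenditure."""
    per_capita = df["total_expenditure"] / df["hh_size"]
    return pd.Series(
        pd.qcut(per_capita.rank(method="first"), n_quantiles, labels=False).astype(int) + 1,
        index=df.index,
        name="quintile",
    )


def preprocess(df: pd.DataFrame, config: Optional[PipelineConfig] = None) -> pd.DataFrame:
    """Deflate, harmonise recall periods and derive unit values and shares."""
    config = config or PipelineConfig()
    out = df.copy()
    out.attrs = dict(df.attrs)
    if config.total_expenditure_is_annual:
        out["total_expenditure"] = out["total_expenditure"] / config.recall_divisor
    out = deflate(out, config.cpi_series, config.base_year)
    out["unit_value"] = compute_unit_value(
        out["cig_expenditure"].to_numpy(), out["cig_quantity"].to_numpy()
    )
    if config.winsorize_unit_values:
        a = config.winsorize_unit_values
        v = out["unit_value"]
        lo, hi = v.quantile(a), v.quantile(1 - a)
        out["unit_value"] = v.clip(lo, hi)
    out["budget_share"] = out["cig_expenditure"] / out["total_expenditure"]
    out["quintile"] = assign_quintiles(out, config.n_quantiles)
    return out


# ---------------------------------------------------------------------------
# weighted descriptive statistics
# ---------------------------------------------------------------------------

def wmean(x, w) -> float:
    x, w = np.asarray(x, float), np.asarray(w, float)
    return float(np.sum(w * x) / np.sum(w))


def wsd(x, w) -> float:
    x, w = np.asarray(x, float), np.asarray(w, float)
    m = wmean(x, w)
    n = len(x)
    if n < 2:
        return float("nan")
    # frequency-weight style small-sample correction
    return float(np.sqrt(np.sum(w * (x - m) ** 2) / np.sum(w) * n / (n - 1)))


def wquantile(x, w, q) -> float:
    """Weighted quantile by inverting the weighted empirical CDF."""
    x, w = np.asarray(x, float), np.asarray(w, float)
    order = np.argsort(x)
    x, w = x[order], w[order]
    cdf = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(q, cdf, x))


def describe(df: pd.DataFrame, config: Optional[PipelineConfig] = None) -> pd.DataFrame:
    """Weighted descriptive table of the outcome variables.

    Unconditional rows cover all records; conditional rows (quantity,
    expenditure, unit value, budget share) cover consuming records only —
    mirroring how household-survey tobacco tables are conventionally
    reported.  Cluster-size rows summarise the survey design.
    """
    if len(df) == 0:
        raise ValidationError("describe() needs a non-empty set of records")
    config = config or PipelineConfig()
    w = df["weight"].to_numpy(float) if config.weighted_describe else np.ones(len(df))
    if not np.any(w > 0):
        raise ValidationError("all survey weights are zero")

    work = df.copy()
    if "budget_share" not in work.columns:
        work["budget_share"] = work["cig_expenditure"] / work["total_expenditure"]
    if "unit_value" not in work.columns:
        work["unit_value"] = compute_unit_value(
            work["cig_expenditure"].to_numpy(), work["cig_quantity"].to_numpy()
        )
    work["consumes"] = (work["cig_quantity"] > 0).astype(float)

    rows = []

    def add(name, values, weights):
        values = np.asarray(values, float)
        rows.append(
            {
                "variable": name,
                "n": int(len(values)),
                "mean": wmean(values, weights),
                "sd": wsd(values, weights),
                "q10": wquantile(values, weights, 0.10),
                "q90": wquantile(values, weights, 0.90),
            }
        )

    add("total_expenditure", work["total_expenditure"], w)
    add("consumes", work["consumes"], w)
    cons = work["consumes"] > 0
    wc = w[cons.to_numpy()]
    if cons.any():
        add("cig_quantity | consuming", work.loc[cons, "cig_quantity"], wc)
        add("cig_expenditure | consuming", work.loc[cons, "cig_expenditure"], wc)
        add("unit_value | consuming", work.loc[cons, "unit_value"], wc)
        add("budget_share | consuming", work.loc[cons, "budget_share"], wc)
    add("budget_share", work["budget_share"], w)

    sizes = work.groupby("cluster_id").size()
    hh = work.groupby("cluster_id")["household_id"].nunique()
    ones = np.ones(len(sizes))
    add("obs_per_cluster", sizes.to_numpy(float), ones)
    add("households_per_cluster", hh.to_numpy(float), ones)
    rows.append(
        {
            "variable": "n_clusters",
            "n": int(work["cluster_id"].nunique()),
            "mean": np.nan, "sd": np.nan, "q10": np.nan, "q90": np.nan,
        }
    )
    rows.append(
        {
            "variable": "n_cluster_years",
            "n": int(work.groupby(["cluster_id", "year"]).ngroups),
            "mean": np.nan, "sd": np.nan, "q10": np.nan, "q90": np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("variable")
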