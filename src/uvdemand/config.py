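"""Run configuration for the unit-value demand pipeline.

A single :class:`PipelineConfig` travels through every stage: data loading,
preprocessing (deflation, recall harmonisation), the two first-stage
regressions, the cluster-level errors-in-variables step, the elasticity
recovery and the bootstrap.  It can be built in code or read from a YAML
file (see :meth:`PipelineConfig.from_yaml`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import yaml

from .errors import ConfigurationError

#: Canonical column names every stage understands.
CANONICAL_COLUMNS = [
    "household_id",
    "cluster_id",
    "year",
    "weight",
    "cig_expenditure",
    "cig_quantity",
    "total_expenditure",
    "hh_size",
    "n_male",
    "head_female",
    "head_educ_years",
    "max_educ_years",
    "urban",
    "share_m_0_5",
    "share_f_0_5",
    "share_m_6_17",
    "share_f_6_17",
    "share_m_18_49",
    "share_f_18_49",
    "share_m_gt49",
    "share_f_gt49",
]

#: Age-sex composition share columns (must sum to one within a record).
SHARE_COLUMNS = [c for c in CANONICAL_COLUMNS if c.startswith("share_")]

#: Columns holding currency amounts, rescaled by deflation.
CURRENCY_COLUMNS = ["cig_expenditure", "total_expenditure", "unit_value"]

FE_MODES = ("cluster_and_year", "year_only")
PSI_FORMULAS = ("separability_exact", "as_printed", "deaton_1997")
WBAR_MODES = ("unconditional", "conditional")
SIGMA10_DIVISORS = ("all", "consumers")
CLUSTER_SIZE_SUMMARIES = ("harmonic", "arithmetic")


@dataclass
class PipelineConfig:
    """Everything needed to re-run an estimation deterministically.

    Parameters
    ----------
    column_map
        Mapping from source-file column names to canonical names.  Columns
        already canonically named need no entry.
    base_year
        Year whose prices all currency values are expressed in.
    cpi_series
        Consumer price index by survey year (any base; ratios are used).
    recall_divisor
        Divisor converting annual totals to weekly equivalents.  365/7
        gives true weekly averages; 52 is also common.
    total_expenditure_is_annual
        If True, total expenditure in the input is an annual recall value
        and is divided by ``recall_divisor`` during preprocessing.
    weighted_describe / weighted_regression
        Whether survey weights apply in the descriptive tables and in the
        first-stage regressions respectively.
    fe_mode_eq1
        ``"cluster_and_year"`` absorbs cluster effects in the unit-value
        equation (needed so the residual variance excludes the spatial
        price signal); ``"year_only"`` estimates it with year dummies only.
    psi_formula
        Variant of the quality-correction formula for the price elasticity
        of the unit value: ``separability_exact`` (ψ̂ = 1/(1+(w̄−φ̂)ζ̂),
        the exact inverse of the second-stage slope under weak
        separability, default), ``as_printed`` (ψ̂ = 1−β̂1(w̄−θ̂)/(β̂1+w̄))
        or ``deaton_1997`` (ψ̂ = 1+ζ̂(θ̂−w̄), the first-order expansion).
    wbar_mode
        Sample mean budget share used in the recovery formulas:
        ``unconditional`` averages over all households including
        non-consumers (matching the unconditional budget-share equation);
        ``conditional`` averages over consuming households only.
    sigma10_divisor
        Cluster-size summary dividing the σ̂10 correction in the EIV slope:
        ``all`` uses the full cluster size n_c (the budget-share average
        runs over every record), ``consumers`` uses n_c+.
    cluster_size_summary
        ``harmonic`` (mean of inverse sizes, appropriate for averaged
        corrections) or ``arithmetic``.
    winsorize_unit_values
        Optional symmetric quantile (e.g. 0.01) at which unit values are
        winsorised before estimation; ``None`` disables trimming.
    """

    column_map: dict = field(default_factory=dict)
    base_year: int = 2017
    cpi_series: dict = field(default_factory=lambda: {2016: 95.7, 2017: 100.0, 2018: 104.1})
    recall_divisor: float = 365.0 / 7.0
    total_expenditure_is_annual: bool = False
    weighted_describe: bool = True
    weighted_regression: bool = False
    fe_mode_eq1: str = "cluster_and_year"
    psi_formula: str = "separability_exact"
    wbar_mode: str = "unconditional"
    sigma10_divisor: str = "all"
    cluster_size_summary: str = "harmonic"
    temporal_clustering: bool = True
    compute_f_tests: bool = True
    robust_se: bool = True
    winsorize_unit_values: Optional[float] = None
    bootstrap_reps: int = 1000
    seed: int = 20170
    n_quantiles: int = 5

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.base_year not in self.cpi_series:
            raise ConfigurationError(
                f"cpi_series must contain the base year {self.base_year}; "
                f"got years {sorted(self.cpi_series)}"
            )
        if self.bootstrap_reps < 1:
            raise ConfigurationError("bootstrap_reps must be >= 1")
        if self.recall_divisor <= 0:
            raise ConfigurationError("recall_divisor must be positive")
        for name, value, allowed in [
            ("fe_mode_eq1", self.fe_mode_eq1, FE_MODES),
            ("psi_formula", self.psi_formula, PSI_FORMULAS),
            ("wbar_mode", self.wbar_mode, WBAR_MODES),
            ("sigma10_divisor", self.sigma10_divisor, SIGMA10_DIVISORS),
            ("cluster_size_summary", self.cluster_size_summary, CLUSTER_SIZE_SUMMARIES),
        ]:
            if value not in allowed:
                raise ConfigurationError(f"{name} must be one of {allowed}, got {value!r}")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        if "cpi_series" in d:
            d["cpi_series"] = {int(k): float(v) for k, v in d["cpi_series"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        return cls.from_dict(raw)
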