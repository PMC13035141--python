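"""Synthetic clustered panel survey with known generating parameters.

The generator draws a three-wave household panel from the structural model
behind the two first-stage equations: a cluster-common log price ln pi_c
(spatial variation, static across waves by default), quality shading of
unit values in expenditure, a budget-share Engel curve, cluster and year
effects, and jointly drawn AR(1) measurement errors in log unit value and
budget share.  Every downstream stage of the pipeline is therefore
testable against known truth without any external download.

Parametrisation notes
---------------------
* ``beta0``, ``theta``, ``gamma0``, ``alpha0`` and the budget-share year
  effects are the coefficients of the UNCONDITIONAL budget-share equation
  (the regression the pipeline runs, zeros included).  Consuming
  households — a ``participation_rate`` Bernoulli draw per household,
  independent of price and expenditure, constant across waves — receive
  conditional mean ``(linear index)/participation_rate``, non-consumers
  get exactly zero, so the unconditional regression is consistent for the
  labelled coefficients.
* The default truth sets ``psi`` on Deaton's weak-separability locus,
  psi = (1 + zeta*theta)/(1 + zeta*wbar) at the calibrated mean share, so
  that the quality-correction recovery is internally consistent; ``psi``
  remains a free field for misspecification experiments.
* Magnitudes are calibrated to a low-income South Asian cigarette market:
  ~15% of households consuming, conditional budget share ~5%, quality
  elasticity ~0.78, weekly household consumption ~NPR 3,500 in 2017
  prices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np
import pandas as pd

from .design import build_design
from .errors import GenerationError
from .survey import assign_quintiles

#: Order of the covariate slope vectors (everything in the design except
#: log expenditure and the year dummies).
GAMMA_ORDER = [
    "ln_hh_size", "ln_hh_size_sq",
    "share_m_0_5", "share_f_0_5", "share_m_6_17", "share_f_6_17",
    "share_m_18_49", "share_f_18_49", "share_m_gt49",
    "head_female", "ln_head_educ", "ln_head_educ_sq",
    "n_male", "ln_max_educ", "ln_max_educ_sq",
    "quintile_2", "quintile_3", "quintile_4", "quintile_5",
    "urban",
]

_GAMMA1_DEFAULT = np.array([
    -0.5774, -0.0059,
    -0.2599, 0.1740, -0.1524, -0.0632, -0.1428, 0.0757, -0.0529,
    0.0624, 0.0229, 0.0169,
    0.0317, -0.0307, -0.0018,
    -0.2475, -0.4552, -0.5647, -0.9139,
    -0.0931,
])

# Budget-share covariate slopes at half the field-typical magnitudes: a
# strictly positive linear share model cannot carry the full observed
# dispersion without leaving (0, 1) for a non-trivial fraction of
# consumers, so the default attenuates covariate effects while keeping
# their signs and relative sizes.
_GAMMA0_DEFAULT = 0.5 * np.array([
    -0.0098, 0.0018,
    -0.0133, -0.0043, -0.0047, -0.0066, -0.0015, -0.0051, 0.0020,
    -0.0035, 0.0005, -0.0004,
    -0.0007, 0.0016, -0.0012,
    -0.0025, -0.0048, -0.0060, -0.0089,
    -0.0018,
])

#: Age-sex composition target means (male/female x 0-5, 6-17, 18-49, >49).
_SHARE_MEANS = np.array([0.0406, 0.0364, 0.1313, 0.1212,
                         0.1840, 0.2512, 0.1185, 0.1169])

MAX_INVALID_SHARE_FRACTION = 0.01


@dataclass
class SyntheticTruth:
    """Generating parameters of the simulated survey."""

    alpha1: float = -3.38852
    alpha0: float = -0.031720
    beta1: float = 0.78
    beta0: float = 0.0066
    gamma1: np.ndarray = field(default_factory=lambda: _GAMMA1_DEFAULT.copy())
    gamma0: np.ndarray = field(default_factory=lambda: _GAMMA0_DEFAULT.copy())
    psi: float = 0.7518
    theta: float = 0.0033
    cluster_price_sd: float = 0.40
    price_wave_sd: float = 0.0
    cluster_fe_sd: float = 0.0005
    share_floor: float = 0.005
    year_effects_uv: tuple = (0.0, 0.1021, 0.0800)
    year_effects_bs: tuple = (0.0, -0.0030, -0.0039)
    sigma11: float = 0.25
    sigma00: float = 2.5e-5
    sigma10: float = 0.00125
    rho_time: float = 0.30
    participation_rate: float = 0.155
    n_clusters: int = 400
    households_per_cluster: float = 15
    n_waves: int = 3
    first_year: int = 2016
    lnx_mean: float = 8.12
    lnx_cluster_sd: float = 0.16
    lnx_household_sd: float = 0.20
    lnx_wave_sd: float = 0.10
    urban_share: float = 0.35
    weight_sd: float = 0.25
    seed: int = 20160

    def __post_init__(self):
        self.gamma1 = np.asarray(self.gamma1, float)
        self.gamma0 = np.asarray(self.gamma0, float)
        self.validate()

    def validate(self) -> None:
        if not (0 < self.participation_rate <= 1):
            raise GenerationError("participation_rate must lie in (0, 1]")
        if abs(self.rho_time) >= 1:
            raise GenerationError("|rho_time| must be < 1")
        if self.sigma11 < 0 or self.sigma00 < 0:
            raise GenerationError("error variances must be non-negative")
        if self.sigma10**2 > self.sigma11 * self.sigma00 + 1e-15:
            raise GenerationError(
                "|sigma10| must not exceed sqrt(sigma11 * sigma00)"
            )
        if len(self.gamma1) != len(GAMMA_ORDER) or len(self.gamma0) != len(GAMMA_ORDER):
            raise GenerationError(
                f"gamma vectors must have length {len(GAMMA_ORDER)} "
                f"(order: {GAMMA_ORDER})"
            )
        if self.n_waves > len(self.year_effects_uv):
            raise GenerationError("year_effects_uv shorter than n_waves")
        if self.n_waves > len(self.year_effects_bs):
            raise GenerationError("year_effects_bs shorter than n_waves")

    def replace(self, **kwargs) -> "SyntheticTruth":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gamma1"] = self.gamma1.tolist()
        d["gamma0"] = self.gamma0.tolist()
        d["year_effects_uv"] = list(self.year_effects_uv)
        d["year_effects_bs"] = list(self.year_effects_bs)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _psd_sqrt(sigma11: float, sigma00: float, sigma10: float) -> np.ndarray:
    cov = np.array([[sigma11, sigma10], [sigma10, sigma00]])
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    return vecs @ np.diag(np.sqrt(vals)) @ vecs.T


def generate(truth: Optional[SyntheticTruth] = None) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a full synthetic survey; identical seed gives identical output.

    Returns a preprocessed-equivalent frame (canonical columns plus
    ``unit_value``, ``budget_share`` and ``quintile``) whose
    ``attrs['deflated_to']`` marks it as already in base-year prices, and
    the truth used.
    """
    truth = truth or SyntheticTruth()
    truth.validate()
    rng = np.random.default_rng(truth.seed)

    C = truth.n_clusters
    T = truth.n_waves
    base = int(np.floor(truth.households_per_cluster))
    frac = truth.households_per_cluster - base
    hh_per_cluster = base + (rng.random(C) < frac).astype(int)
    H = int(hh_per_cluster.sum())

    cluster_of_hh = np.repeat(np.arange(C), hh_per_cluster)

    # cluster-level draws
    ln_pi_c = rng.normal(0.0, truth.cluster_price_sd, C)
    f_c = rng.normal(0.0, truth.cluster_fe_sd, C)
    urban_c = (rng.random(C) < truth.urban_share).astype(int)
    a_c = rng.normal(0.0, truth.lnx_cluster_sd, C)
    weight_c = np.exp(rng.normal(0.0, truth.weight_sd, C))
    weight_c /= weight_c.mean()

    # household-level covariates (constant across waves)
    hh_size = 1 + rng.poisson(3.97, H)
    hh_size = np.clip(hh_size, 1, 22)
    n_male = rng.binomial(hh_size, 0.475)
    shares = rng.dirichlet(_SHARE_MEANS * 6.0, H)
    head_female = (rng.random(H) < 0.21).astype(int)
    head_educ = np.where(rng.random(H) < 0.35, 0, rng.poisson(6.2, H))
    head_educ = np.clip(head_educ, 0, 15)
    max_educ = np.clip(head_educ + rng.poisson(3.0, H), 0, 15)
    b_h = rng.normal(0.0, truth.lnx_household_sd, H)
    smoker = rng.random(H) < truth.participation_rate

    # expand to household x wave records
    rows_hh = np.repeat(np.arange(H), T)
    rows_cl = cluster_of_hh[rows_hh]
    wave = np.tile(np.arange(T), H)
    years = truth.first_year + wave

    ln_x = (truth.lnx_mean + a_c[rows_cl] + b_h[rows_hh]
            + rng.normal(0.0, truth.lnx_wave_sd, H * T))
    total_expenditure = np.exp(ln_x)

    df = pd.DataFrame({
        "household_id": rows_hh,
        "cluster_id": rows_cl,
        "year": years,
        "weight": weight_c[rows_cl],
        "cig_expenditure": 0.0,
        "cig_quantity": 0.0,
        "total_expenditure": total_expenditure,
        "hh_size": hh_size[rows_hh],
        "n_male": n_male[rows_hh],
        "head_female": head_female[rows_hh],
        "head_educ_years": head_educ[rows_hh],
        "max_educ_years": max_educ[rows_hh],
        "urban": urban_c[rows_cl],
    })
    for j, c in enumerate(["share_m_0_5", "share_f_0_5", "share_m_6_17",
                           "share_f_6_17", "share_m_18_49", "share_f_18_49",
                           "share_m_gt49", "share_f_gt49"]):
        df[c] = shares[rows_hh, j]

    df["quintile"] = assign_quintiles(df)
    X, names = build_design(df)
    cov_idx = [names.index(c) for c in GAMMA_ORDER if c in names]
    cov_names = [c for c in GAMMA_ORDER if c in names]
    g1 = np.array([truth.gamma1[GAMMA_ORDER.index(c)] for c in cov_names])
    g0 = np.array([truth.gamma0[GAMMA_ORDER.index(c)] for c in cov_names])
    Z = X[:, cov_idx]

    ln_price = ln_pi_c[rows_cl]
    if truth.price_wave_sd > 0:
        shift = rng.normal(0.0, truth.price_wave_sd, (C, T))
        ln_price = ln_price + shift[rows_cl, wave]

    mean_lnv = (truth.alpha1 + truth.beta1 * ln_x + Z @ g1
                + truth.psi * ln_price
                + np.asarray(truth.year_effects_uv)[wave])
    mean_w_unc = (truth.alpha0 + truth.beta0 * ln_x + Z @ g0
                  + truth.theta * ln_price + f_c[rows_cl]
                  + np.asarray(truth.year_effects_bs)[wave])

    # AR(1) bivariate measurement errors for consuming households
    is_smoker_row = smoker[rows_hh]
    L = _psd_sqrt(truth.sigma11, truth.sigma00, truth.sigma10)
    n_s = int(smoker.sum())
    eta = rng.standard_normal((n_s, T, 2))
    u = np.empty((n_s, T, 2))
    u[:, 0, :] = eta[:, 0, :] @ L.T
    rho = truth.rho_time
    innov = np.sqrt(1.0 - rho**2)
    for t in range(1, T):
        u[:, t, :] = rho * u[:, t - 1, :] + innov * (eta[:, t, :] @ L.T)

    u1 = np.zeros(H * T)
    u0 = np.zeros(H * T)
    smoker_rows = np.flatnonzero(is_smoker_row)
    # rows are ordered household-major, wave-minor; map smoker block back
    u1[smoker_rows] = u[:, :, 0].ravel()
    u0[smoker_rows] = u[:, :, 1].ravel()

    p = truth.participation_rate
    w = np.zeros(H * T)
    v = np.zeros(H * T)
    # conditional mean share, floored at a small positive level: Engel
    # curves for a habit good flatten near zero rather than turn negative
    m_cond = np.maximum(mean_w_unc[is_smoker_row] / p, truth.share_floor)
    w[is_smoker_row] = m_cond + u0[is_smoker_row]
    v[is_smoker_row] = np.exp(mean_lnv[is_smoker_row] + u1[is_smoker_row])

    invalid = is_smoker_row & ((w <= 0) | (w >= 1))
    n_cons = int(is_smoker_row.sum())
    if n_cons and invalid.sum() > MAX_INVALID_SHARE_FRACTION * n_cons:
        raise GenerationError(
            f"{invalid.sum()}/{n_cons} consuming records have budget shares "
            "outside (0, 1); rescale alpha0/sigma00/gamma0 toward smaller "
            "shares or noise"
        )
    w[invalid] = np.clip(w[invalid], 1e-6, 1 - 1e-6)

    cig_expenditure = w * total_expenditure
    with np.errstate(divide="ignore", invalid="ignore"):
        cig_quantity = np.where(is_smoker_row, cig_expenditure / v, 0.0)

    df["cig_expenditure"] = cig_expenditure
    df["cig_quantity"] = cig_quantity
    df["budget_share"] = w
    df["unit_value"] = np.where(is_smoker_row, v, np.nan)
    df.attrs["deflated_to"] = 2017
    df.attrs["n_invalid_shares"] = int(invalid.sum())
    return df, truth


def implied_elasticities(truth: Optional[SyntheticTruth] = None,
                         wbar_mode: str = "unconditional",
                         n_clusters: int = 1500,
                         households_per_cluster: float = 20.0) -> tuple[float, float]:
    """Elasticities the generator implies: eps_p = theta/wbar - psi and
    eps_I = 1 + beta0/wbar - beta1, with wbar the expected budget share
    under ``wbar_mode`` estimated from a large generated sample."""
    truth = truth or SyntheticTruth()
    big = truth.replace(
        n_clusters=n_clusters,
        households_per_cluster=households_per_cluster,
        seed=(truth.seed + 999_983) % 2**31,
    )
    df, _ = generate(big)
    if wbar_mode == "conditional":
        wbar = float(df.loc[df["cig_quantity"] > 0, "budget_share"].mean())
    else:
        wbar = float(df["budget_share"].mean())
    eps_p = truth.theta / wbar - truth.psi
    eps_i = 1.0 + truth.beta0 / wbar - truth.beta1
    return eps_p, eps_i
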