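"""Quality-corrected price and expenditure elasticities.

Unit values conflate market price with chosen quality: richer households
buy dearer varieties (quality shading, slope ``beta1`` of log unit value
on log expenditure).  Deaton's correction recovers the price elasticities
of the unit value (``psi``) and of the budget share (``theta``) from the
second-stage slope ``phi`` and the first-stage Engel-curve coefficients,
then converts them to the price elasticity of quantity demanded

    eps_p = theta / wbar - psi

and the expenditure (income-proxy) elasticity

    eps_I = 1 + beta0 / wbar - beta1.

Three variants of the psi formula are provided.  ``separability_exact``
(default), psi = (1 + zeta*theta)/(1 + zeta*wbar), is the exact inverse of
the second-stage relation phi = theta/psi combined with the weak-
separability link between quality shading and the price response; it is
the only variant that recovers the generating psi of an internally
consistent simulated survey.  ``deaton_1997``, psi = 1 + zeta*(theta -
wbar), is its first-order expansion, adequate when zeta*wbar and
zeta*theta are small (typical for broad food groups, not for a small-share
good like cigarettes).  ``as_printed``, psi = 1 - beta1*(wbar - theta) /
(beta1 + wbar), follows the arrangement printed in some applied work.  All
variants coincide at theta = wbar (no price response of the share beyond
pass-through) and when beta1 = 0 (no quality shading), where psi = 1.

Inference is by a cluster bootstrap: survey-design clusters are resampled
with replacement, all waves of a cluster moving together, and the entire
two-stage pipeline is re-run per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import PipelineConfig
from .errors import EstimationError
from .first_stage import fit_first_stage
from .second_stage import aggregate_clusters, eiv_phi
from .survey import preprocess

MAX_DROPPED_FRACTION = 0.20


# ---------------------------------------------------------------------------
# recovery formulas
# ---------------------------------------------------------------------------

def zeta(beta1_hat: float, beta0_hat: float, wbar: float) -> float:
    """Quality-response ratio: zeta = beta1 / (beta0 + wbar (1 - beta1))."""
    denom = beta0_hat + wbar * (1.0 - beta1_hat)
    if denom == 0:
        raise EstimationError("zeta denominator beta0 + wbar(1-beta1) is zero")
    return beta1_hat / denom


def theta(phi_hat: float, zeta_hat: float, wbar: float) -> float:
    """Price slope of the budget share: theta = phi / (1 + (wbar - phi) zeta)."""
    denom = 1.0 + (wbar - phi_hat) * zeta_hat
    if denom == 0:
        raise EstimationError("theta denominator 1 + (wbar - phi) zeta is zero")
    return phi_hat / denom


def psi(theta_hat: float, zeta_hat: float, beta1_hat: float, wbar: float,
        psi_formula: str = "separability_exact") -> float:
    """Price elasticity of the unit value under the chosen formula variant."""
    if psi_formula == "as_printed":
        denom = beta1_hat + wbar
        if denom == 0:
            raise EstimationError("psi (as_printed) denominator beta1 + wbar is zero")
        return 1.0 - beta1_hat * (wbar - theta_hat) / denom
    if psi_formula == "deaton_1997":
        return 1.0 + zeta_hat * (theta_hat - wbar)
    if psi_formula == "separability_exact":
        denom = 1.0 + zeta_hat * wbar
        if denom == 0:
            raise EstimationError("psi (separability_exact) denominator 1 + zeta wbar is zero")
        return (1.0 + zeta_hat * theta_hat) / denom
    raise EstimationError(f"unknown psi_formula {psi_formula!r}")


def price_elasticity(theta_hat: float, psi_hat: float, wbar: float) -> float:
    """eps_p = theta / wbar - psi."""
    if wbar <= 0:
        raise EstimationError("mean budget share must be positive")
    return theta_hat / wbar - psi_hat


def expenditure_elasticity(beta0_hat: float, beta1_hat: float, wbar: float) -> float:
    """eps_I = 1 + beta0 / wbar - beta1."""
    if wbar <= 0:
        raise EstimationError("mean budget share must be positive")
    return 1.0 + beta0_hat / wbar - beta1_hat


def recover_elasticities(beta0_hat: float, beta1_hat: float, phi_hat: float,
                         wbar: float, psi_formula: str = "separability_exact") -> dict:
    """Chain Eqs. zeta -> theta -> psi -> elasticities from first/second-stage
    estimates; returns all intermediates."""
    z = zeta(beta1_hat, beta0_hat, wbar)
    t = theta(phi_hat, z, wbar)
    p = psi(t, z, beta1_hat, wbar, psi_formula)
    return {
        "zeta": z,
        "theta": t,
        "psi": p,
        "eps_p": price_elasticity(t, p, wbar),
        "eps_I": expenditure_elasticity(beta0_hat, beta1_hat, wbar),
    }


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------

@dataclass
class ElasticityResult:
    """Point estimates, intermediates and bootstrap inference."""

    wbar: float
    zeta_hat: float
    theta_hat: float
    psi_hat: float
    phi_hat: float
    beta1_hat: float
    beta0_hat: float
    eps_p: float
    eps_I: float
    se_p: float = np.nan
    se_I: float = np.nan
    ci_p: tuple = (np.nan, np.nan)
    ci_I: tuple = (np.nan, np.nan)
    n_boot: int = 0
    n_dropped: int = 0
    seed: Optional[int] = None
    psi_variants: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("eps_p", "eps_I"):
            if not np.isfinite(getattr(self, name)):
                raise EstimationError(f"{name} is not finite")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("expenditure_elasticity", self.eps_I, self.se_I, *self.ci_I),
            ("price_elasticity", self.eps_p, self.se_p, *self.ci_p),
            ("mean_budget_share", self.wbar, np.nan, np.nan, np.nan),
            ("phi", self.phi_hat, np.nan, np.nan, np.nan),
            ("zeta", self.zeta_hat, np.nan, np.nan, np.nan),
            ("theta", self.theta_hat, np.nan, np.nan, np.nan),
            ("psi", self.psi_hat, np.nan, np.nan, np.nan),
        ]
        return pd.DataFrame(
            rows, columns=["term", "estimate", "se", "ci_low", "ci_high"]
        ).set_index("term")

    def to_dict(self) -> dict:
        d = {
            "wbar": self.wbar, "zeta": self.zeta_hat, "theta": self.theta_hat,
            "psi": self.psi_hat, "phi": self.phi_hat,
            "beta1": self.beta1_hat, "beta0": self.beta0_hat,
            "eps_p": self.eps_p, "eps_I": self.eps_I,
            "se_p": self.se_p, "se_I": self.se_I,
            "ci_p": list(self.ci_p), "ci_I": list(self.ci_I),
            "n_boot": self.n_boot, "n_dropped": self.n_dropped,
            "seed": self.seed, "psi_variants": self.psi_variants,
        }
        return d


# ---------------------------------------------------------------------------
# pipeline core
# ---------------------------------------------------------------------------

def compute_wbar(df: pd.DataFrame, config: PipelineConfig) -> float:
    w = df["budget_share"].to_numpy(float)
    if config.wbar_mode == "conditional":
        mask = df["cig_quantity"].to_numpy(float) > 0
        w = w[mask]
    if config.weighted_regression:
        wt = df["weight"].to_numpy(float)
        wt = wt[mask] if config.wbar_mode == "conditional" else wt
        return float(np.sum(wt * w) / np.sum(wt))
    return float(np.mean(w))


def _point_pipeline(df: pd.DataFrame, config: PipelineConfig,
                    corrected: bool = True) -> dict:
    """Run first stage -> aggregation -> EIV -> recovery on a preprocessed
    frame; the single code path shared by point estimation and bootstrap."""
    fit = fit_first_stage(df, config)
    agg = aggregate_clusters(df, fit)
    eiv = eiv_phi(agg, fit.sigma10_hat, fit.sigma11_hat, config, corrected=corrected)
    wbar = compute_wbar(df, config)
    rec = recover_elasticities(fit.beta0_hat, fit.beta1_hat, eiv.phi_hat,
                               wbar, config.psi_formula)
    return {"fit": fit, "aggregates": agg, "eiv": eiv, "wbar": wbar, **rec}


def cluster_bootstrap(df: pd.DataFrame, config: PipelineConfig,
                      n_boot: Optional[int] = None,
                      seed: Optional[int] = None,
                      resampler: Optional[Callable] = None,
                      corrected: bool = True) -> dict:
    """Resample survey-design clusters with replacement and re-run the full
    pipeline per replicate.

    All waves of a cluster move together, preserving within-cluster
    dependence and the common-price structure.  Replicates where the
    corrected EIV denominator is non-positive (or the first stage fails)
    are dropped and counted; more than 20% dropped raises
    :class:`EstimationError`.

    ``resampler(rng, cluster_ids)`` may be supplied to control the drawn
    cluster multiset (e.g. the identity for testing); by default clusters
    are drawn iid with replacement.
    """
    n_boot = int(config.bootstrap_reps if n_boot is None else n_boot)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    clusters = pd.Index(df["cluster_id"].unique())
    positions = {c: np.flatnonzero((df["cluster_id"] == c).to_numpy()) for c in clusters}
    hh_codes, _ = pd.factorize(df["household_id"], use_na_sentinel=False)
    n_hh = int(hh_codes.max()) + 1

    light = config.replace(compute_f_tests=False, robust_se=False)

    reps = {"eps_p": [], "eps_I": [], "phi": [], "theta": [], "psi": [], "zeta": []}
    dropped = 0
    arr = df.reset_index(drop=True)
    for b in range(n_boot):
        if resampler is not None:
            sample = np.asarray(resampler(rng, clusters.to_numpy()))
        else:
            sample = clusters.to_numpy()[rng.integers(0, len(clusters), len(clusters))]
        rows = np.concatenate([positions[c] for c in sample])
        sizes = np.array([len(positions[c]) for c in sample])
        rep = arr.iloc[rows].copy()
        rep["cluster_id"] = np.repeat(np.arange(len(sample)), sizes)
        # copies of the same household in re-drawn clusters stay distinct
        rep["household_id"] = hh_codes[rows] + n_hh * np.repeat(
            np.arange(len(sample)), sizes
        )
        rep.index = pd.RangeIndex(len(rep))
        try:
            out = _point_pipeline(rep, light, corrected=corrected)
        except EstimationError:
            dropped += 1
            continue
        for key in ("eps_p", "eps_I", "theta", "psi", "zeta"):
            reps[key].append(out[key])
        reps["phi"].append(out["eiv"].phi_hat)

    if n_boot > 1 and dropped > MAX_DROPPED_FRACTION * n_boot:
        raise EstimationError(
            f"{dropped}/{n_boot} bootstrap replicates failed the "
            "errors-in-variables step; the design has too little "
            "between-cluster price signal for reliable inference"
        )
    return {"replicates": {k: np.asarray(v) for k, v in reps.items()},
            "n_boot": n_boot, "n_dropped": dropped, "seed": seed}


# ---------------------------------------------------------------------------
# top-level estimator
# ---------------------------------------------------------------------------

class DeatonElasticityModel(BaseEstimator):
    """Two-stage unit-value demand model with quality correction.

    A scikit-learn-style estimator over a preprocessed household-wave
    frame (see :func:`uvdemand.survey.preprocess`; :meth:`fit` will
    preprocess automatically if derived columns are absent).

    Parameters mirror :class:`uvdemand.config.PipelineConfig`; set
    ``bootstrap_reps=0`` to skip inference.

    Attributes (after :meth:`fit`)
    ------------------------------
    first_stage_ : FirstStageFit
    aggregates_ : DataFrame of cluster-level purged means
    eiv_ : EivResult
    wbar_, zeta_, theta_, psi_, phi_, eps_p_, eps_I_ : floats
    result_ : ElasticityResult with bootstrap SEs and percentile CIs
    """

    def __init__(self, fe_mode_eq1: str = "cluster_and_year",
                 psi_formula: str = "separability_exact",
                 wbar_mode: str = "unconditional",
                 sigma10_divisor: str = "all",
                 cluster_size_summary: str = "harmonic",
                 temporal_clustering: bool = True,
                 weighted_regression: bool = False,
                 corrected: bool = True,
                 bootstrap_reps: int = 0,
                 seed: int = 0):
        self.fe_mode_eq1 = fe_mode_eq1
        self.psi_formula = psi_formula
        self.wbar_mode = wbar_mode
        self.sigma10_divisor = sigma10_divisor
        self.cluster_size_summary = cluster_size_summary
        self.temporal_clustering = temporal_clustering
        self.weighted_regression = weighted_regression
        self.corrected = corrected
        self.bootstrap_reps = bootstrap_reps
        self.seed = seed

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            fe_mode_eq1=self.fe_mode_eq1,
            psi_formula=self.psi_formula,
            wbar_mode=self.wbar_mode,
            sigma10_divisor=self.sigma10_divisor,
            cluster_size_summary=self.cluster_size_summary,
            temporal_clustering=self.temporal_clustering,
            weighted_regression=self.weighted_regression,
            bootstrap_reps=max(self.bootstrap_reps, 1),
            seed=self.seed,
        )

    def fit(self, df: pd.DataFrame, y=None):
        config = self._config()
        if "quintile" not in df.columns or "budget_share" not in df.columns:
            df = preprocess(df, config)
        out = _point_pipeline(df, config, corrected=self.corrected)
        self.first_stage_ = out["fit"]
        self.aggregates_ = out["aggregates"]
        self.eiv_ = out["eiv"]
        self.wbar_ = out["wbar"]
        self.zeta_ = out["zeta"]
        self.theta_ = out["theta"]
        self.psi_ = out["psi"]
        self.phi_ = out["eiv"].phi_hat
        self.eps_p_ = out["eps_p"]
        self.eps_I_ = out["eps_I"]

        variants = {
            v: psi(self.theta_, self.zeta_, self.first_stage_.beta1_hat, self.wbar_, v)
            for v in ("separability_exact", "as_printed", "deaton_1997")
        }
        result = ElasticityResult(
            wbar=self.wbar_, zeta_hat=self.zeta_, theta_hat=self.theta_,
            psi_hat=self.psi_, phi_hat=self.phi_,
            beta1_hat=self.first_stage_.beta1_hat,
            beta0_hat=self.first_stage_.beta0_hat,
            eps_p=self.eps_p_, eps_I=self.eps_I_,
            seed=self.seed, psi_variants=variants,
        )
        if self.bootstrap_reps > 0:
            boot = cluster_bootstrap(df, config, n_boot=self.bootstrap_reps,
                                     seed=self.seed, corrected=self.corrected)
            reps = boot["replicates"]
            if len(reps["eps_p"]) >= 2:
                result.se_p = float(np.std(reps["eps_p"], ddof=1))
                result.se_I = float(np.std(reps["eps_I"], ddof=1))
                result.ci_p = tuple(np.percentile(reps["eps_p"], [2.5, 97.5]))
                result.ci_I = tuple(np.percentile(reps["eps_I"], [2.5, 97.5]))
            result.n_boot = boot["n_boot"]
            result.n_dropped = boot["n_dropped"]
            self.bootstrap_replicates_ = reps
        self.result_ = result
        return self
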