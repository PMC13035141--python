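"""First-stage regressions of the unit-value demand model.

Two pooled-OLS equations over the household x wave panel:

* unit-value equation: ``ln v = a1 + b1 ln x + Z g1 + psi ln pi_c + y_t + u1``
  estimated on consuming records, by default with cluster absorbers so the
  unobserved cluster price (and any other cluster-level component) is
  swept out of the residual;
* budget-share equation: ``w = a0 + b0 ln x + Z g0 + theta ln pi_c + f_c +
  y_t + u0`` estimated on the full sample, zeros included, with cluster
  fixed effects.

The unobserved log cluster price ``ln pi_c`` is omitted from both designs;
its coefficients (psi, theta) are recovered later from between-cluster
variation.  Fixed effects are absorbed by within-cluster demeaning, which
is numerically identical to explicit cluster dummies; coefficient standard
errors are household-clustered, so serial correlation of a household's
errors across the three waves is accounted for.

Residual (co)variances feed the errors-in-variables correction of the
second stage.  With temporal clustering on (default) they are computed
from household-level sums of residuals across waves, so that the
correction terms match the sampling variance of cluster-averaged errors
under arbitrary within-household serial correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .config import PipelineConfig
from .design import LN_X, build_design, year_effect_names
from .errors import EstimationError
from .survey import preprocess

MIN_INTERSECTION = 10


# ---------------------------------------------------------------------------
# low-level fixed-effect OLS machinery
# ---------------------------------------------------------------------------

def _group_codes(values) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(values, use_na_sentinel=False)
    return codes, len(uniques)


def within_demean(A: np.ndarray, codes: np.ndarray, n_groups: int,
                  weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Subtract (weighted) group means from each column of ``A``."""
    A2 = A if A.ndim == 2 else A[:, None]
    if weights is None:
        counts = np.bincount(codes, minlength=n_groups).astype(float)
        sums = np.zeros((n_groups, A2.shape[1]))
        np.add.at(sums, codes, A2)
        means = sums / counts[:, None]
    else:
        wsum = np.bincount(codes, weights=weights, minlength=n_groups)
        sums = np.zeros((n_groups, A2.shape[1]))
        np.add.at(sums, codes, A2 * weights[:, None])
        means = sums / wsum[:, None]
    out = A2 - means[codes]
    return out if A.ndim == 2 else out[:, 0]


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # small R diagonal in the (unpivoted) QR flags columns that add no rank
    _, Rm = np.linalg.qr(X)
    diag = np.abs(np.diag(Rm))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[j] for j in range(len(names)) if diag[j] < tol]
    if bad:
        raise EstimationError(f"singular design; collinear columns: {bad}")


def _fe_ols(y: np.ndarray, X: np.ndarray, names: list[str],
            absorb_codes: Optional[np.ndarray], n_absorb: int,
            household: np.ndarray,
            weights: Optional[np.ndarray] = None,
            robust_se: bool = True) -> dict:
    """OLS with optional absorbed group effects and household-clustered SEs.

    Returns coefficients, within residuals, purged values ``y - X beta``
    (systematic household/temporal parts removed, group-level components
    retained), fit statistics and the clustered covariance.
    """
    n = len(y)
    if weights is not None:
        sw = np.sqrt(weights)
    dropped_names: list[str] = []
    if absorb_codes is not None:
        Xd = within_demean(X, absorb_codes, n_absorb, weights)
        yd = within_demean(y, absorb_codes, n_absorb, weights)
        # group-constant regressors (e.g. an urban indicator defined at the
        # cluster level) vanish under demeaning; their effect is absorbed
        norms = np.sqrt(np.sum(Xd**2, axis=0))
        scale = np.sqrt(np.sum(X**2, axis=0))
        keep = norms > 1e-8 * np.maximum(scale, 1.0)
        dropped_names = [nm for nm, k in zip(names, keep) if not k]
        names = [nm for nm, k in zip(names, keep) if k]
        X, Xd = X[:, keep], Xd[:, keep]
        k_absorbed = n_absorb
        use_names = list(names)
    else:
        # explicit intercept instead of absorbed effects; constant columns
        # are collinear with it and dropped
        spread = X.max(axis=0) - X.min(axis=0)
        keep = spread > 1e-12
        dropped_names = [nm for nm, k in zip(names, keep) if not k]
        names = [nm for nm, k in zip(names, keep) if k]
        X = X[:, keep]
        Xd = np.column_stack([np.ones(n), X])
        yd = y
        k_absorbed = 0
        use_names = ["const"] + list(names)
    if weights is not None:
        Xw, yw = Xd * sw[:, None], yd * sw
    else:
        Xw, yw = Xd, yd
    _check_rank(Xw, use_names)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yd - Xd @ beta
    if absorb_codes is None:
        coefs = dict(zip(names, beta[1:]))
        intercept = beta[0]
        purged = y - X @ beta[1:] - intercept
    else:
        coefs = dict(zip(names, beta))
        intercept = 0.0
        purged = y - X @ beta

    k = Xd.shape[1]
    dof = n - k - k_absorbed
    ssr = float(resid @ resid) if weights is None else float((resid * weights) @ resid)
    tss_y = yd - (np.average(yd, weights=weights) if weights is not None else yd.mean())
    tss = float(tss_y @ tss_y) if weights is None else float((tss_y * weights) @ tss_y)
    r2 = 1.0 - ssr / tss if tss > 0 else np.nan
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / max(dof, 1) if np.isfinite(r2) else np.nan

    # household-clustered sandwich on the demeaned data
    hcodes, n_h = _group_codes(household)
    if robust_se:
        S = np.zeros((n_h, k))
        np.add.at(S, hcodes, Xw * (resid * (sw if weights is not None else 1.0))[:, None])
        meat = S.T @ S
        bread = np.linalg.inv(XtX)
        adj = (n_h / max(n_h - 1, 1)) * ((n - 1) / max(dof, 1))
        vcov = adj * bread @ meat @ bread
        se = np.sqrt(np.diag(vcov))
    else:
        se = np.full(k, np.nan)
    if absorb_codes is None:
        se_map = dict(zip(use_names, se))
        se_coefs = {nm: se_map[nm] for nm in names}
    else:
        se_coefs = dict(zip(names, se))

    return {
        "coefs": pd.Series(coefs),
        "se": pd.Series(se_coefs),
        "dropped": dropped_names,
        "intercept": intercept,
        "resid": resid,
        "purged": purged,
        "n": n,
        "k": k,
        "k_absorbed": k_absorbed,
        "dof": dof,
        "ssr": ssr,
        "r2": r2,
        "r2_adj": r2_adj,
        "n_households": n_h,
    }


def _fe_f_test(y, X, names, codes, n_groups, household, weights, fit_u) -> dict:
    """Joint F test of the absorbed cluster effects (classical form)."""
    fit_r = _fe_ols(y, X, names, None, 0, household, weights)
    q = n_groups - 1 - len(fit_u.get("dropped", []))
    dfd = fit_u["dof"]
    if fit_u["ssr"] <= 0 or dfd <= 0:
        return {"F": np.inf, "df1": q, "df2": dfd, "p": 0.0}
    F = ((fit_r["ssr"] - fit_u["ssr"]) / q) / (fit_u["ssr"] / dfd)
    return {"F": float(F), "df1": int(q), "df2": int(dfd),
            "p": float(stats.f.sf(F, q, dfd))}


# ---------------------------------------------------------------------------
# fitted first stage
# ---------------------------------------------------------------------------

@dataclass
class FirstStageFit:
    """Coefficients, purged residuals and error (co)variances of both
    first-stage equations."""

    beta1_hat: float = np.nan
    gamma1_hat: pd.Series = field(default_factory=pd.Series)
    se1: pd.Series = field(default_factory=pd.Series)
    year_effects1: pd.Series = field(default_factory=pd.Series)
    beta0_hat: float = np.nan
    gamma0_hat: pd.Series = field(default_factory=pd.Series)
    se0: pd.Series = field(default_factory=pd.Series)
    year_effects0: pd.Series = field(default_factory=pd.Series)
    resid1: pd.Series = field(default_factory=pd.Series)   # within residuals, consumers
    resid0: pd.Series = field(default_factory=pd.Series)   # within residuals, all records
    purged1: pd.Series = field(default_factory=pd.Series)  # ln v - b1 ln x - Z g1 - y_t
    purged0: pd.Series = field(default_factory=pd.Series)  # w - b0 ln x - Z g0 - y_t
    household1: pd.Series = field(default_factory=pd.Series)
    household0: pd.Series = field(default_factory=pd.Series)
    cluster1: pd.Series = field(default_factory=pd.Series)
    cluster0: pd.Series = field(default_factory=pd.Series)
    sigma11_hat: float = np.nan
    sigma00_hat: float = np.nan
    sigma10_hat: float = np.nan
    n1: int = 0
    n0: int = 0
    dof1: int = 0
    dof0: int = 0
    r2_1: float = np.nan
    r2_2: float = np.nan
    r2_adj_1: float = np.nan
    r2_adj_0: float = np.nan
    fe_f_tests: dict = field(default_factory=dict)
    clusters_without_consumers: int = 0
    fe_mode_eq1: str = "cluster_and_year"

    def coefficient_table(self) -> pd.DataFrame:
        """Both equations side by side: estimate, clustered SE, stars."""

        def stars(est, se):
            if not np.isfinite(se) or se == 0:
                return ""
            z = abs(est / se)
            return "***" if z > 2.576 else "**" if z > 1.96 else "*" if z > 1.645 else ""

        idx = sorted(set(self.gamma1_hat.index) | set(self.gamma0_hat.index),
                     key=lambda s: (s != LN_X, s))
        rows = []
        for name in idx:
            e1, s1 = self.gamma1_hat.get(name, np.nan), self.se1.get(name, np.nan)
            e0, s0 = self.gamma0_hat.get(name, np.nan), self.se0.get(name, np.nan)
            rows.append({
                "term": name,
                "unit_value_estimate": e1, "unit_value_se": s1,
                "unit_value_sig": stars(e1, s1),
                "budget_share_estimate": e0, "budget_share_se": s0,
                "budget_share_sig": stars(e0, s0),
            })
        return pd.DataFrame(rows).set_index("term")


class UnitValueRegression(BaseEstimator):
    """Fixed-effects OLS of log unit value on log expenditure and covariates.

    Parameters
    ----------
    fe_mode : str
        ``"cluster_and_year"`` absorbs cluster effects (default);
        ``"year_only"`` fits with an intercept and year dummies only.
    weighted : bool
        Use survey weights in estimation.
    """

    def __init__(self, fe_mode: str = "cluster_and_year", weighted: bool = False,
                 compute_f_test: bool = True, robust_se: bool = True):
        self.fe_mode = fe_mode
        self.weighted = weighted
        self.compute_f_test = compute_f_test
        self.robust_se = robust_se

    def fit(self, df: pd.DataFrame, y=None):
        consumers = df["unit_value"].notna() & (df["unit_value"] > 0)
        sub = df.loc[consumers]
        if sub["cluster_id"].nunique() < 2 or len(sub) < 2:
            raise EstimationError("unit-value equation needs >=2 consuming "
                                  "records in >=2 clusters")
        self.clusters_without_consumers_ = int(
            df["cluster_id"].nunique() - sub["cluster_id"].nunique()
        )
        yv = np.log(sub["unit_value"].to_numpy(float))
        X, names = build_design(sub)
        codes, n_groups = _group_codes(sub["cluster_id"].to_numpy())
        weights = sub["weight"].to_numpy(float) if self.weighted else None
        household = sub["household_id"].to_numpy()
        if self.fe_mode == "cluster_and_year":
            res = _fe_ols(yv, X, names, codes, n_groups, household, weights,
                          robust_se=self.robust_se)
            self.fe_f_ = (
                _fe_f_test(yv, X, names, codes, n_groups, household, weights, res)
                if self.compute_f_test else None
            )
        else:
            res = _fe_ols(yv, X, names, None, 0, household, weights,
                          robust_se=self.robust_se)
            self.fe_f_ = None
        self._store(res, names, sub.index, sub)
        return self

    def _store(self, res, names, index, sub):
        ynames = year_effect_names(names)
        self.coefs_ = res["coefs"]
        self.se_ = res["se"]
        self.beta_ = float(res["coefs"][LN_X])
        self.year_effects_ = res["coefs"][ynames]
        self.resid_ = pd.Series(res["resid"], index=index)
        self.purged_ = pd.Series(res["purged"], index=index)
        self.household_ = sub["household_id"].reindex(index)
        self.cluster_ = sub["cluster_id"].reindex(index)
        self.n_ = res["n"]
        self.dof_ = res["dof"]
        self.r2_ = res["r2"]
        self.r2_adj_ = res["r2_adj"]
        self.k_ = res["k"]
        self.k_absorbed_ = res["k_absorbed"]


class BudgetShareRegression(BaseEstimator):
    """Cluster-fixed-effects OLS of the cigarette budget share on the full
    sample (non-consuming households enter with share zero)."""

    def __init__(self, weighted: bool = False, compute_f_test: bool = True,
                 robust_se: bool = True):
        self.weighted = weighted
        self.compute_f_test = compute_f_test
        self.robust_se = robust_se

    def fit(self, df: pd.DataFrame, y=None):
        if df["cluster_id"].nunique() < 2 or len(df) < 2:
            raise EstimationError("budget-share equation needs >=2 records "
                                  "in >=2 clusters")
        yv = df["budget_share"].to_numpy(float)
        X, names = build_design(df)
        codes, n_groups = _group_codes(df["cluster_id"].to_numpy())
        weights = df["weight"].to_numpy(float) if self.weighted else None
        household = df["household_id"].to_numpy()
        res = _fe_ols(yv, X, names, codes, n_groups, household, weights,
                      robust_se=self.robust_se)
        self.fe_f_ = (
            _fe_f_test(yv, X, names, codes, n_groups, household, weights, res)
            if self.compute_f_test else None
        )
        ynames = year_effect_names(names)
        self.coefs_ = res["coefs"]
        self.se_ = res["se"]
        self.beta_ = float(res["coefs"][LN_X])
        self.year_effects_ = res["coefs"][ynames]
        self.resid_ = pd.Series(res["resid"], index=df.index)
        self.purged_ = pd.Series(res["purged"], index=df.index)
        self.household_ = df["household_id"]
        self.cluster_ = df["cluster_id"]
        self.n_ = res["n"]
        self.dof_ = res["dof"]
        self.r2_ = res["r2"]
        self.r2_adj_ = res["r2_adj"]
        self.k_ = res["k"]
        self.k_absorbed_ = res["k_absorbed"]
        return self


# ---------------------------------------------------------------------------
# module-level wrappers and residual covariances
# ---------------------------------------------------------------------------

def fit_unit_value_eq(df: pd.DataFrame, config: Optional[PipelineConfig] = None,
                      fit: Optional[FirstStageFit] = None) -> FirstStageFit:
    config = config or PipelineConfig()
    est = UnitValueRegression(fe_mode=config.fe_mode_eq1,
                              weighted=config.weighted_regression,
                              compute_f_test=config.compute_f_tests,
                              robust_se=config.robust_se).fit(df)
    out = fit or FirstStageFit()
    out.fe_mode_eq1 = config.fe_mode_eq1
    out.beta1_hat = est.beta_
    out.gamma1_hat = est.coefs_
    out.se1 = est.se_
    out.year_effects1 = est.year_effects_
    out.resid1 = est.resid_
    out.purged1 = est.purged_
    out.household1 = est.household_
    out.cluster1 = est.cluster_
    out.n1 = est.n_
    out.dof1 = est.dof_
    out.r2_1 = est.r2_
    out.r2_adj_1 = est.r2_adj_
    out.clusters_without_consumers = est.clusters_without_consumers_
    if est.fe_f_ is not None:
        out.fe_f_tests["unit_value"] = est.fe_f_
    out._k1 = est.k_
    out._g1 = est.k_absorbed_
    return out


def fit_budget_share_eq(df: pd.DataFrame, config: Optional[PipelineConfig] = None,
                        fit: Optional[FirstStageFit] = None) -> FirstStageFit:
    config = config or PipelineConfig()
    est = BudgetShareRegression(weighted=config.weighted_regression,
                                compute_f_test=config.compute_f_tests,
                                robust_se=config.robust_se).fit(df)
    out = fit or FirstStageFit()
    out.beta0_hat = est.beta_
    out.gamma0_hat = est.coefs_
    out.se0 = est.se_
    out.year_effects0 = est.year_effects_
    out.resid0 = est.resid_
    out.purged0 = est.purged_
    out.household0 = est.household_
    out.cluster0 = est.cluster_
    out.n0 = est.n_
    out.dof0 = est.dof_
    out.r2_2 = est.r2_
    out.r2_adj_0 = est.r2_adj_
    if est.fe_f_ is not None:
        out.fe_f_tests["budget_share"] = est.fe_f_
    out._k0 = est.k_
    out._g0 = est.k_absorbed_
    return out


def _clustered_moment(a: np.ndarray, b: np.ndarray, household: np.ndarray,
                      n_clusters_absorbed: int, k: int, dof_naive: int,
                      temporal: bool) -> float:
    """(Co)variance of residual series, household-summed across waves.

    With ``temporal`` the estimator is sum_h (sum_t a_ht)(sum_t b_ht) / dof,
    whose expectation matches the per-observation contribution of serially
    correlated errors to a cluster-average error.  Demeaning within G
    absorbed clusters shrinks household sums by a factor (H - G)/H in
    expectation, so the degrees of freedom are T_bar (H - G) - k with
    T_bar the average number of waves per household; without temporal
    clustering, the naive cross-product sum over n - k - G is used.
    """
    if temporal:
        hcodes, n_h = _group_codes(household)
        sa = np.bincount(hcodes, weights=a, minlength=n_h)
        sb = np.bincount(hcodes, weights=b, minlength=n_h)
        total = float(sa @ sb)
        t_bar = len(a) / n_h
        dof = t_bar * (n_h - n_clusters_absorbed) - k
    else:
        total = float(a @ b)
        dof = dof_naive
    return total / max(dof, 1.0)


def residual_covariances(fit: FirstStageFit,
                         config: Optional[PipelineConfig] = None) -> tuple[float, float, float]:
    """Estimate (sigma11, sigma00, sigma10) from first-stage residuals.

    sigma11 comes from the consuming sample, sigma00 from the full
    budget-share sample, and sigma10 from their intersection (consuming
    records, where both residuals exist).  All are degrees-of-freedom
    corrected by n - k - (number of absorbed effects).  When
    ``config.temporal_clustering`` is set (default) residuals are summed
    within household across waves before forming products, so serial
    correlation inflates or deflates the estimates exactly as it does the
    cluster-average error terms that the EIV step corrects for.
    """
    config = config or PipelineConfig()
    if len(fit.resid1) == 0 or len(fit.resid0) == 0:
        raise EstimationError("both first-stage equations must be fitted "
                              "before residual covariances")
    temporal = config.temporal_clustering

    r1 = fit.resid1.to_numpy(float)
    h1 = fit.household1.to_numpy()
    k1 = getattr(fit, "_k1", 0)
    g1 = getattr(fit, "_g1", 0)
    dof1 = fit.dof1
    if fit.fe_mode_eq1 == "year_only":
        # the raw residual still carries the cluster price signal; measure
        # the idiosyncratic error from within-cluster deviations
        codes, n_g = _group_codes(fit.cluster1.to_numpy())
        r1 = within_demean(r1, codes, n_g)
        resid1_within = pd.Series(r1, index=fit.resid1.index)
        dof1 = max(fit.dof1 - n_g, 1)
        g1 = n_g
    else:
        resid1_within = fit.resid1
    fit.sigma11_hat = _clustered_moment(r1, r1, h1, g1, k1, dof1, temporal)

    r0 = fit.resid0.to_numpy(float)
    h0 = fit.household0.to_numpy()
    fit.sigma00_hat = _clustered_moment(
        r0, r0, h0, getattr(fit, "_g0", 0), getattr(fit, "_k0", 0),
        fit.dof0, temporal,
    )

    common = fit.resid1.index.intersection(fit.resid0.index)
    if len(common) < MIN_INTERSECTION:
        raise EstimationError(
            f"only {len(common)} records have both residuals; "
            f"need >= {MIN_INTERSECTION} for the cross-equation covariance"
        )
    a = resid1_within.loc[common].to_numpy(float)
    b = fit.resid0.loc[common].to_numpy(float)
    hh = fit.household1.loc[common].to_numpy()
    dof10 = len(common) - k1 - g1
    fit.sigma10_hat = _clustered_moment(a, b, hh, g1, k1, dof10, temporal)
    return fit.sigma11_hat, fit.sigma00_hat, fit.sigma10_hat


def fit_first_stage(df: pd.DataFrame,
                    config: Optional[PipelineConfig] = None) -> FirstStageFit:
    """Fit both equations and the residual (co)variances on a preprocessed
    frame."""
    config = config or PipelineConfig()
    fit = FirstStageFit()
    fit_unit_value_eq(df, config, fit)
    fit_budget_share_eq(df, config, fit)
    residual_covariances(fit, config)
    return fit
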