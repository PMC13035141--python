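"""Cluster-level aggregation and the errors-in-variables slope.

Purged household values (log unit value and budget share net of estimated
expenditure, covariate and year effects) are averaged within each
survey-design cluster, pooling the three waves.  The cluster averages

    y1_c  (mean purged log unit value over consuming records, n_c+ of them)
    y0_c  (mean purged budget share over all records, n_c of them)

carry the common cluster price signal plus averaged idiosyncratic error.
Regressing y0 on y1 across clusters would be attenuated by that averaged
measurement error; the corrected slope subtracts its estimated moments:

    phi = (cov(y1, y0) - sigma10 / n~) / (var(y1) - sigma11 / n~+)

with n~ and n~+ cluster-size summaries (harmonic means by default, since
the error contribution of a cluster scales with the inverse of its size).
The sigma10 correction divides by the full cluster size: y0_c averages
over all n_c records while only the n_c+ consuming ones carry the
cross-equation error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import EstimationError
from .first_stage import FirstStageFit


@dataclass
class EivResult:
    """Corrected second-stage slope and its ingredients."""

    phi_hat: float
    cov_raw: float
    var_raw: float
    correction10: float
    correction11: float
    n_clusters_used: int
    n_tilde: float
    n_tilde_plus: float

    @property
    def phi_naive(self) -> float:
        """Uncorrected cov/var slope (attenuated by measurement error)."""
        return self.cov_raw / self.var_raw


def aggregate_clusters(df: pd.DataFrame, fit: FirstStageFit) -> pd.DataFrame:
    """Average purged values to the survey-design cluster level.

    Returns one row per cluster with ``y1c`` (NaN when the cluster has no
    consuming record in any wave), ``y0c``, the full record count ``n_c``
    and the consuming record count ``n_c_plus``; waves are pooled within
    cluster.
    """
    if len(fit.purged0) == 0:
        raise EstimationError("first stage must be fitted before aggregation")
    g0 = pd.DataFrame({
        "y0": fit.purged0.to_numpy(float),
        "cluster_id": fit.cluster0.to_numpy(),
    }).groupby("cluster_id")["y0"]
    agg = pd.DataFrame({"y0c": g0.mean(), "n_c": g0.size()})
    g1 = pd.DataFrame({
        "y1": fit.purged1.to_numpy(float),
        "cluster_id": fit.cluster1.to_numpy(),
    }).groupby("cluster_id")["y1"]
    agg["y1c"] = g1.mean()
    agg["n_c_plus"] = g1.size().reindex(agg.index).fillna(0).astype(int)
    agg = agg.reset_index()[["cluster_id", "y1c", "y0c", "n_c", "n_c_plus"]]
    return agg


def _size_summary(sizes: np.ndarray, how: str) -> float:
    sizes = np.asarray(sizes, float)
    if how == "harmonic":
        return float(len(sizes) / np.sum(1.0 / sizes))
    return float(np.mean(sizes))


def eiv_phi(aggregates: pd.DataFrame, sigma10_hat: float, sigma11_hat: float,
            config: Optional[PipelineConfig] = None,
            corrected: bool = True) -> EivResult:
    """Errors-in-variables slope of cluster budget share on cluster unit value.

    Clusters lacking a consuming record carry no unit-value signal and are
    excluded.  With ``corrected=False`` the raw cov/var slope is returned
    (useful for quantifying attenuation).
    """
    config = config or PipelineConfig()
    usable = aggregates.dropna(subset=["y1c"])
    usable = usable[usable["n_c_plus"] >= 1]
    if len(usable) < 3:
        raise EstimationError(
            f"only {len(usable)} clusters with unit-value signal; need >= 3"
        )
    y1 = usable["y1c"].to_numpy(float)
    y0 = usable["y0c"].to_numpy(float)
    cov_raw = float(np.cov(y1, y0, ddof=1)[0, 1])
    var_raw = float(np.var(y1, ddof=1))

    n_tilde_plus = _size_summary(usable["n_c_plus"], config.cluster_size_summary)
    if config.sigma10_divisor == "all":
        n_tilde = _size_summary(usable["n_c"], config.cluster_size_summary)
    else:
        n_tilde = n_tilde_plus

    c10 = sigma10_hat / n_tilde if corrected else 0.0
    c11 = sigma11_hat / n_tilde_plus if corrected else 0.0
    denom = var_raw - c11
    if denom <= 0:
        raise EstimationError(
            "corrected between-cluster variance of unit values is not "
            f"positive ({denom:.3g}); more or larger clusters are needed "
            "for the errors-in-variables step"
        )
    phi = (cov_raw - c10) / denom
    return EivResult(
        phi_hat=phi, cov_raw=cov_raw, var_raw=var_raw,
        correction10=c10, correction11=c11,
        n_clusters_used=int(len(usable)),
        n_tilde=n_tilde, n_tilde_plus=n_tilde_plus,
    )
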