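"""Density/abundance estimation with variance components and log-normal CIs.

The point estimator follows the standard point-transect form adapted to
camera snapshots: with n detections, S total trigger opportunities across
cameras, a wedge of area a0 = (theta/360) pi w^2 sampled per opportunity and
mean detectability p within the wedge,

    D = n / (S a0 p),        N = D A.

Uncertainty has two components combined on the CV scale:
cv_total^2 = cv_encounter^2 + cv_detection^2, where the encounter-rate CV
comes from the empirical, effort-weighted between-camera variance of n_k/e_k
(cameras are the sampling units) and the detection CV from the delta-method
variance of p. Confidence intervals are log-normal with a t quantile on
Satterthwaite degrees of freedom, the standard construction for skewed
density estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .detection import DetectionFit
from .observations import EffortTable

__all__ = [
    "AbundanceEstimate",
    "encounter_rate_stats",
    "estimate_abundance",
    "lognormal_ci",
    "variance_decomposition",
    "SingleCameraError",
    "EstimationError",
]


class SingleCameraError(ValueError):
    """Encounter-rate variance needs >= 2 cameras with positive effort."""


class EstimationError(ValueError):
    """Abundance estimation failed (e.g. p_hat <= 0 or zero effort)."""


@dataclass
class AbundanceEstimate:
    """Abundance/density for one stratum x period with variance components."""

    stratum: str
    period: str
    n_obs: int
    D_hat: float  # animals per km^2
    N_hat: float  # animals in the surveyed area
    cv_total: float
    cv_encounter: float
    cv_detection: float
    ci_low: float
    ci_high: float
    df: float  # Satterthwaite degrees of freedom
    area_km2: float
    model_label: str = ""

    @property
    def var_N(self) -> float:
        return (self.N_hat * self.cv_total) ** 2

    @property
    def se_N(self) -> float:
        return self.N_hat * self.cv_total


def encounter_rate_stats(
    per_camera_counts: Mapping[str, float],
    effort: EffortTable,
    effort_column: str = "effective_effort",
) -> tuple[float, float, float, int]:
    """Encounter rate and its effort-weighted between-camera variance.

    rate = sum(n_k) / sum(e_k); the variance estimator is the standard
    between-unit form for unequal effort,

        var(rate) = K/(K-1) * sum e_k^2 (n_k/e_k - rate)^2 / (sum e_k)^2,

    with df = K - 1. Cameras absent from ``per_camera_counts`` contribute
    n_k = 0; cameras with zero effort are dropped (they carry no information
    and an observation there would be inconsistent).
    """
    tbl = effort.table
    e = tbl[effort_column].to_numpy(dtype=float)
    cams = list(tbl["camera_id"])
    n = np.array([float(per_camera_counts.get(c, 0.0)) for c in cams])
    if np.any((e <= 0) & (n > 0)):
        raise EstimationError("observations recorded at a camera with zero effort")
    keep = e > 0
    e, n = e[keep], n[keep]
    K = len(e)
    if K == 0:
        raise EstimationError("zero total effort")
    if K == 1:
        raise SingleCameraError("encounter-rate variance undefined with a single camera")
    E = e.sum()
    rate = n.sum() / E
    var = K / (K - 1) * float(np.sum(e ** 2 * (n / e - rate) ** 2)) / E ** 2
    cv = math.sqrt(var) / rate if rate > 0 else float("nan")
    return rate, var, cv, K - 1


def lognormal_ci(
    N_hat: float,
    cv_total: float,
    alpha: float = 0.1,
    df: float = math.inf,
) -> tuple[float, float]:
    """Log-normal confidence interval (N/C, N*C), C = exp(q sqrt(ln(1+cv^2))).

    ``q`` is the two-sided t quantile at level ``alpha`` with ``df`` degrees
    of freedom (normal quantile when df is infinite). A zero CV collapses the
    interval to the point estimate with a warning.
    """
    if cv_total < 0:
        raise ValueError("cv_total must be >= 0")
    if cv_total == 0:
        warnings.warn("cv = 0: degenerate confidence interval")
        return N_hat, N_hat
    if df < 1:
        raise ValueError("df must be >= 1")
    if math.isinf(df):
        q = stats.norm.ppf(1.0 - alpha / 2.0)
    else:
        q = stats.t.ppf(1.0 - alpha / 2.0, df)
    C = math.exp(q * math.sqrt(math.log1p(cv_total ** 2)))
    return N_hat / C, N_hat * C


def _satterthwaite_df(cv_e: float, df_e: float, cv_p: float, df_p: float) -> float:
    cv2 = cv_e ** 2 + cv_p ** 2
    if cv2 == 0:
        return math.inf
    denom = 0.0
    if cv_e > 0 and df_e > 0:
        denom += cv_e ** 4 / df_e
    if cv_p > 0 and df_p > 0:
        denom += cv_p ** 4 / df_p
    return cv2 ** 2 / denom if denom > 0 else math.inf


def estimate_abundance(
    per_camera_counts: Mapping[str, float],
    effort: EffortTable,
    fit: DetectionFit,
    theta: float = 50.0,
    area_km2: float = 6.2,
    alpha: float = 0.1,
    stratum: str = "",
    period: str = "",
) -> AbundanceEstimate:
    """Abundance estimate for one stratum from counts, effort and a fitted
    detection function.

    The covered area per trigger opportunity is a0 = (theta/360) pi w^2 (m^2);
    D = n / (S a0 p_hat) with S the summed (unscaled) trigger opportunities.
    """
    n = float(sum(per_camera_counts.values()))
    S = effort.total_snapshots
    if S <= 0:
        raise EstimationError("zero total effort")
    if fit.p_hat <= 0:
        raise EstimationError("p_hat <= 0")
    w = fit.w
    a0_m2 = (theta / 360.0) * math.pi * w ** 2
    D_m2 = n / (S * a0_m2 * fit.p_hat)
    D_km2 = D_m2 * 1e6
    N_hat = D_km2 * area_km2

    _, _, cv_e, df_e = encounter_rate_stats(per_camera_counts, effort)
    cv_p = fit.cv_detection
    df_p = max(1, fit.n_obs - fit.config.n_params)
    cv_total = math.sqrt(cv_e ** 2 + cv_p ** 2)
    df = _satterthwaite_df(cv_e, df_e, cv_p, df_p)
    if cv_total > 0:
        lo, hi = lognormal_ci(N_hat, cv_total, alpha=alpha, df=df)
    else:
        lo = hi = N_hat
    return AbundanceEstimate(
        stratum=stratum,
        period=period,
        n_obs=int(n),
        D_hat=D_km2,
        N_hat=N_hat,
        cv_total=cv_total,
        cv_encounter=cv_e,
        cv_detection=cv_p,
        ci_low=lo,
        ci_high=hi,
        df=df,
        area_km2=area_km2,
        model_label=fit.config.label,
    )


def variance_decomposition(estimate: AbundanceEstimate) -> dict[str, float]:
    """Fractions of squared CV attributable to encounter rate vs. detection."""
    cv2 = estimate.cv_total ** 2
    if cv2 <= 0:
        raise ValueError("cv_total must be > 0 to decompose variance")
    return {
        "encounter": estimate.cv_encounter ** 2 / cv2,
        "detection": estimate.cv_detection ** 2 / cv2,
    }
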