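"""Point-transect detection-function fitting.

Each camera snapshot is treated as a (partial-circle) point sample: an
animal at radial distance r inside the viewshed is recorded with probability
g(r), where g(0) = 1 and g declines with distance. The radial distances of
recorded animals then follow the density

    f(r) = r g(r) / integral_0^w u g(u) du,      0 <= r <= w,

with w the truncation distance. g is modelled as a key function (uniform,
half-normal or hazard-rate) optionally multiplied by a small series
expansion (cosine, simple polynomial or Hermite polynomial in r/w),
rescaled so g(0) = 1. Parameters are fitted by maximum likelihood with a
multi-start quasi-Newton optimizer; fits whose g is not monotone
nonincreasing (or leaves [0, 1]) on a grid are flagged and excluded from
model selection rather than silently clamped.

The average detection probability within the sampled wedge is
p = (2/w^2) integral_0^w r g(r) dr; for the half-normal key without
adjustments it has the closed form p = (2 sigma^2/w^2)(1 - exp(-w^2/(2 sigma^2))),
used as an internal cross-check of the quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.polynomial import hermite_e
from scipy import optimize, stats

__all__ = [
    "KEYS",
    "EXPANSIONS",
    "DetectionConfig",
    "DetectionFit",
    "GofResult",
    "DomainError",
    "NumericalDegeneracyError",
    "InsufficientDataError",
    "FitFailureError",
    "detection_g",
    "detection_pdf",
    "fit_detection",
    "average_p",
    "half_normal_average_p",
    "gof_chi2",
]

KEYS = ("uniform", "half_normal", "hazard_rate")
EXPANSIONS = ("none", "cosine", "simple_polynomial", "hermite_polynomial")

_QUAD_NODES, _QUAD_WEIGHTS = np.polynomial.legendre.leggauss(128)
_MONOTONE_GRID_N = 100
_MONOTONE_TOL = 1e-6


class DomainError(ValueError):
    """Distance outside [0, w]."""


class NumericalDegeneracyError(ValueError):
    """Detection integral vanished; parameters are degenerate."""


class InsufficientDataError(ValueError):
    """Too few distances after truncation to fit a detection function."""


class FitFailureError(RuntimeError):
    """No optimizer start converged."""


@dataclass(frozen=True)
class DetectionConfig:
    """A detection model: key function, series expansion, and truncation."""

    key: str
    expansion: str = "none"
    n_adjust: int = 0
    truncation_w: float = 40.0

    def __post_init__(self) -> None:
        if self.key not in KEYS:
            raise ValueError(f"key must be one of {KEYS}")
        if self.expansion not in EXPANSIONS:
            raise ValueError(f"expansion must be one of {EXPANSIONS}")
        if self.truncation_w <= 0:
            raise ValueError("truncation_w must be > 0")
        if self.expansion == "none" and self.n_adjust != 0:
            raise ValueError("expansion 'none' requires n_adjust = 0")
        if self.expansion != "none" and not 1 <= self.n_adjust <= 2:
            raise ValueError("series expansions use 1-2 adjustment terms")

    @property
    def n_key_params(self) -> int:
        return {"uniform": 0, "half_normal": 1, "hazard_rate": 2}[self.key]

    @property
    def n_params(self) -> int:
        return self.n_key_params + self.n_adjust

    @property
    def label(self) -> str:
        if self.expansion == "none":
            return self.key
        return f"{self.key}+{self.expansion}({self.n_adjust})"


@dataclass
class GofResult:
    """Binned chi-square goodness of fit for a fitted detection function."""

    chi2: float
    df: int
    p_value: float
    bin_edges: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    computable: bool = True


@dataclass
class DetectionFit:
    """A fitted detection model with likelihood, AIC and mean detectability."""

    config: DetectionConfig
    params: dict
    param_vector: np.ndarray
    loglik: float
    aic: float
    p_hat: float
    var_p_hat: float
    n_obs: int
    converged: bool
    monotone_ok: bool
    n_zero_adjusted: int = 0
    gof: GofResult | None = None

    @property
    def w(self) -> float:
        return self.config.truncation_w

    @property
    def cv_detection(self) -> float:
        if not np.isfinite(self.var_p_hat) or self.var_p_hat <= 0:
            return 0.0
        return math.sqrt(self.var_p_hat) / self.p_hat

    def g(self, r):
        return detection_g(r, self.config, self.param_vector)

    def pdf(self, r):
        return detection_pdf(r, self.config, self.param_vector)


# ---------------------------------------------------------------------------
# model evaluation


def _params_to_vector(config: DetectionConfig, params: dict) -> np.ndarray:
    """Natural-scale params dict -> internal unconstrained vector."""
    vec = []
    if config.key == "half_normal":
        vec.append(math.log(params["sigma"]))
    elif config.key == "hazard_rate":
        vec.append(math.log(params["sigma"]))
        vec.append(math.log(params["shape"] - 1.0))
    vec.extend(params.get("adjustments", ()))
    return np.asarray(vec, dtype=float)


def _vector_to_params(config: DetectionConfig, vec: np.ndarray) -> dict:
    out: dict = {}
    i = 0
    if config.key == "half_normal":
        out["sigma"] = math.exp(vec[0])
        i = 1
    elif config.key == "hazard_rate":
        out["sigma"] = math.exp(vec[0])
        out["shape"] = 1.0 + math.exp(vec[1])
        i = 2
    out["adjustments"] = list(vec[i:])
    return out


def _key_g(r: np.ndarray, config: DetectionConfig, vec: np.ndarray) -> np.ndarray:
    if config.key == "uniform":
        return np.ones_like(r)
    if config.key == "half_normal":
        sigma = math.exp(vec[0])
        return np.exp(-(r ** 2) / (2.0 * sigma ** 2))
    # hazard-rate: g(r) = 1 - exp(-(r/sigma)^(-b)); g(0) = 1 in the limit
    sigma = math.exp(vec[0])
    b = 1.0 + math.exp(vec[1])
    with np.errstate(divide="ignore", over="ignore"):
        z = np.where(r > 0, (r / sigma) ** (-b), np.inf)
    return -np.expm1(-z)


def _series_matrix(x: np.ndarray, config: DetectionConfig) -> np.ndarray:
    """Columns s_j(x), j = 1..n_adjust, for the configured expansion."""
    cols = []
    for j in range(1, config.n_adjust + 1):
        if config.expansion == "cosine":
            cols.append(np.cos(j * np.pi * x))
        elif config.expansion == "simple_polynomial":
            cols.append(x ** (2 * j))
        elif config.expansion == "hermite_polynomial":
            order = 2 * j + 2  # He_4, He_6
            coeffs = np.zeros(order + 1)
            coeffs[order] = 1.0
            cols.append(hermite_e.hermeval(x, coeffs))
        else:  # pragma: no cover
            raise ValueError(config.expansion)
    return np.column_stack(cols) if cols else np.empty((len(x), 0))


def _raw_g(r: np.ndarray, config: DetectionConfig, vec: np.ndarray) -> np.ndarray:
    """key(r) * (1 + sum a_j s_j(r/w)), rescaled so g(0) = 1. May be negative."""
    w = config.truncation_w
    g = _key_g(r, config, vec)
    if config.n_adjust:
        a = vec[config.n_key_params:]
        s = _series_matrix(r / w, config)
        g = g * (1.0 + s @ a)
        s0 = _series_matrix(np.zeros(1), config)
        denom = 1.0 + float((s0 @ a)[0])
        if denom == 0.0:
            raise NumericalDegeneracyError("adjustment series vanishes at r = 0")
        g = g / denom
    return g


def detection_g(r, config: DetectionConfig, params) -> np.ndarray | float:
    """Detection probability g(r) for 0 <= r <= w; g(0) = 1 by construction.

    ``params`` is either the natural-scale dict ({"sigma": ..., "shape": ...,
    "adjustments": [...]}) or the internal parameter vector. Values are not
    clamped: a parameterization whose g leaves [0, 1] is caught by the fit's
    monotonicity/range check, never silently repaired.
    """
    vec = params if isinstance(params, np.ndarray) else _params_to_vector(config, params)
    arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(arr < 0) or np.any(arr > config.truncation_w):
        raise DomainError(f"distances must lie in [0, {config.truncation_w}]")
    out = _raw_g(arr, config, vec)
    return out if np.ndim(r) else float(out[0])


def _mu(config: DetectionConfig, vec: np.ndarray) -> float:
    """integral_0^w r g(r) dr by 128-node Gauss-Legendre quadrature."""
    w = config.truncation_w
    r = 0.5 * w * (_QUAD_NODES + 1.0)
    vals = r * _raw_g(r, config, vec)
    return float(0.5 * w * np.dot(_QUAD_WEIGHTS, vals))


def detection_pdf(r, config: DetectionConfig, params) -> np.ndarray | float:
    """Radial-distance density f(r) = r g(r) / integral_0^w u g(u) du."""
    vec = params if isinstance(params, np.ndarray) else _params_to_vector(config, params)
    mu = _mu(config, vec)
    if not np.isfinite(mu) or mu <= 1e-300:
        raise NumericalDegeneracyError("normalizing integral of r*g(r) is zero")
    arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(arr < 0) or np.any(arr > config.truncation_w):
        raise DomainError(f"distances must lie in [0, {config.truncation_w}]")
    out = arr * _raw_g(arr, config, vec) / mu
    return out if np.ndim(r) else float(out[0])


def average_p(fit_or_config, params=None, w: float | None = None) -> float:
    """Mean detection probability over the sampled wedge, (2/w^2) ∫ r g dr."""
    if isinstance(fit_or_config, DetectionFit):
        config, vec = fit_or_config.config, fit_or_config.param_vector
    else:
        config = fit_or_config
        vec = params if isinstance(params, np.ndarray) else _params_to_vector(config, params)
    if w is not None and w != config.truncation_w:
        config = replace(config, truncation_w=w)
    return 2.0 * _mu(config, vec) / config.truncation_w ** 2


def half_normal_average_p(sigma: float, w: float) -> float:
    """Closed form for the half-normal key: (2 sigma^2/w^2)(1 - exp(-w^2/(2 sigma^2)))."""
    return 2.0 * sigma ** 2 / w ** 2 * (-math.expm1(-(w ** 2) / (2.0 * sigma ** 2)))


# ---------------------------------------------------------------------------
# fitting


def _prepare_distances(
    distances: Sequence[float], w: float, zero_offset: float
) -> tuple[np.ndarray, int]:
    r = np.asarray(distances, dtype=float)
    if np.any(r < 0):
        raise DomainError("negative distances")
    r = r[r <= w]
    n_zero = int(np.sum(r == 0.0))
    if n_zero:
        # f(0) = 0 exactly, so zero distances (measurement resolution) would
        # contribute -inf; offset them to half the 0.5 m recording resolution
        r = np.where(r == 0.0, zero_offset, r)
    return r, n_zero


def _nll(vec: np.ndarray, r: np.ndarray, config: DetectionConfig) -> float:
    try:
        g = _raw_g(r, config, vec)
        mu = _mu(config, vec)
    except (NumericalDegeneracyError, OverflowError):
        return 1e10
    if not np.isfinite(mu) or mu <= 1e-300 or np.any(g <= 0):
        return 1e10
    ll = np.sum(np.log(r) + np.log(g)) - len(r) * math.log(mu)
    return -float(ll) if np.isfinite(ll) else 1e10


def _monotone_ok(config: DetectionConfig, vec: np.ndarray) -> bool:
    grid = np.linspace(0.0, config.truncation_w, _MONOTONE_GRID_N)
    g = _raw_g(grid, config, vec)
    if np.any(g < -_MONOTONE_TOL) or np.any(g > 1.0 + _MONOTONE_TOL):
        return False
    return bool(np.all(np.diff(g) <= _MONOTONE_TOL))


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h * h)
    return H


def _delta_var_p(config: DetectionConfig, vec: np.ndarray, nll) -> float:
    """Delta-method variance of p_hat from the inverse numerical Hessian."""
    k = len(vec)
    if k == 0:
        return 0.0
    H = _numerical_hessian(nll, vec)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return float("nan")
    if np.any(np.diag(cov) < 0):
        return float("nan")
    h = 1e-5
    grad = np.zeros(k)
    for i in range(k):
        e = np.zeros(k); e[i] = h
        grad[i] = (
            2.0 * (_mu(config, vec + e) - _mu(config, vec - e)) / config.truncation_w ** 2 / (2 * h)
        )
    return float(grad @ cov @ grad)


def _starts(config: DetectionConfig, r: np.ndarray) -> list[np.ndarray]:
    sd = float(np.std(r)) or 1.0
    n_adj = config.n_adjust
    if config.key == "uniform":
        return [np.zeros(n_adj)]
    starts = []
    for s0 in (sd / 2.0, sd, 2.0 * sd):
        head = [math.log(s0)]
        if config.key == "hazard_rate":
            head.append(0.0)  # shape b0 = 2
        starts.append(np.concatenate([head, np.zeros(n_adj)]))
    return starts


def fit_detection(
    distances: Sequence[float],
    config: DetectionConfig,
    zero_offset: float = 0.25,
) -> DetectionFit:
    """Maximum-likelihood fit of a detection model to radial distances.

    Distances beyond ``config.truncation_w`` are truncated; exact zeros are
    offset to ``zero_offset`` metres (half the field measurement resolution)
    and counted in ``n_zero_adjusted``. Optimization is multi-start L-BFGS-B
    with scale starts sigma0 in {sd/2, sd, 2 sd}; the fit is deterministic.
    A fit whose g(r) is non-monotone or leaves [0, 1] on a 100-point grid is
    returned with ``monotone_ok=False`` so model selection can reject it.
    """
    r, n_zero = _prepare_distances(distances, config.truncation_w, zero_offset)
    if len(r) < 10:
        raise InsufficientDataError(
            f"{len(r)} distances after truncation at {config.truncation_w}; need >= 10"
        )

    nll = lambda v: _nll(v, r, config)
    best = None
    if config.n_params == 0:
        best = optimize.OptimizeResult(x=np.zeros(0), fun=nll(np.zeros(0)), success=True)
    else:
        for x0 in _starts(config, r):
            res = optimize.minimize(nll, x0, method="L-BFGS-B")
            if res.fun >= 1e9:
                continue
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise FitFailureError(f"{config.label}: no start converged")

    vec = np.asarray(best.x, dtype=float)
    loglik = -float(best.fun)
    k = config.n_params
    p_hat = average_p(config, vec)
    var_p = _delta_var_p(config, vec, nll) if k else 0.0
    return DetectionFit(
        config=config,
        params=_vector_to_params(config, vec),
        param_vector=vec,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * k,
        p_hat=p_hat,
        var_p_hat=var_p,
        n_obs=len(r),
        converged=bool(best.success) or best.fun < 1e9,
        monotone_ok=_monotone_ok(config, vec),
        n_zero_adjusted=n_zero,
    )


# ---------------------------------------------------------------------------
# goodness of fit


def _detect_resolution(r: np.ndarray) -> float:
    """Largest grid step the distances are all multiples of (0 if none)."""
    for delta in (1.0, 0.5, 0.25, 0.1):
        if np.all(np.abs(r / delta - np.round(r / delta)) < 1e-6):
            return delta
    return 0.0


def gof_chi2(
    fit: DetectionFit,
    distances: Sequence[float],
    n_bins: int = 5,
    zero_offset: float = 0.25,
    resolution: float | None = None,
) -> GofResult:
    """Binned chi-square goodness of fit against the fitted radial density.

    Starts from ``n_bins`` equal-width bins on [0, w]; bins with expected
    count < 5 are merged into their right neighbour (the last bin merges
    left). df = (#bins - 1 - #free parameters), floored at 1. If fewer than
    3 bins survive merging the result is flagged not computable.

    Field distances are usually recorded on a grid (rangefinder resolution),
    which puts point masses exactly on equal-width cutpoints and spuriously
    inflates the statistic. Interior cutpoints are therefore shifted by half
    the measurement resolution so every atom — and the interval of true
    distances it stands for — falls strictly inside one bin. ``resolution``
    is auto-detected from the data when not given.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    raw = np.asarray(distances, dtype=float)
    if resolution is None:
        resolution = _detect_resolution(raw[raw <= fit.w]) if len(raw) else 0.0
    r, _ = _prepare_distances(distances, fit.w, zero_offset)
    edges = np.linspace(0.0, fit.w, n_bins + 1)
    if resolution > 0:
        edges[1:-1] += resolution / 2.0

    # expected bin probabilities from the fitted density, by quadrature per bin
    def bin_prob(lo: float, hi: float) -> float:
        x = 0.5 * (hi - lo) * (_QUAD_NODES + 1.0) + lo
        return float(0.5 * (hi - lo) * np.dot(_QUAD_WEIGHTS, fit.pdf(x)))

    n = len(r)
    probs = np.array([bin_prob(edges[i], edges[i + 1]) for i in range(n_bins)])
    probs = probs / probs.sum()
    obs = np.histogram(r, bins=edges)[0].astype(float)

    # merge deficient bins left-to-right into the right neighbour
    edge_list = list(edges)
    probs = list(probs)
    obs = list(obs)
    i = 0
    while i < len(probs):
        if n * probs[i] < 5.0 and len(probs) > 1:
            if i + 1 < len(probs):
                probs[i + 1] += probs[i]
                obs[i + 1] += obs[i]
                del probs[i], obs[i]
                del edge_list[i + 1]
            else:
                probs[i - 1] += probs[i]
                obs[i - 1] += obs[i]
                del probs[i], obs[i]
                del edge_list[i]
                i -= 1  # re-check the enlarged last bin
        else:
            i += 1

    obs_arr = np.asarray(obs)
    exp_arr = n * np.asarray(probs)
    chi2 = float(np.sum((obs_arr - exp_arr) ** 2 / exp_arr))
    df = max(1, len(obs_arr) - 1 - fit.config.n_params)
    computable = len(obs_arr) >= 3
    p = float(stats.chi2.sf(chi2, df)) if computable else float("nan")
    return GofResult(
        chi2=chi2,
        df=df,
        p_value=p,
        bin_edges=np.asarray(edge_list),
        observed=obs_arr,
        expected=exp_arr,
        computable=computable,
    )


def plot_fit(fit: DetectionFit, distances: Sequence[float], ax=None, n_bins: int = 5):
    """Histogram of distances with the fitted g(r) overlaid (simple export)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    r = np.asarray(distances, dtype=float)
    r = r[r <= fit.w]
    # scale histogram so bar heights are comparable to g(r)
    counts, edges = np.histogram(r, bins=n_bins, range=(0.0, fit.w))
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    dens = counts / counts.sum() / widths
    expected_dens = fit.pdf(centers)
    scale = np.max(expected_dens) or 1.0
    ax.bar(centers, dens / scale, width=widths, alpha=0.4, label="observed")
    grid = np.linspace(0, fit.w, 200)
    ax.plot(grid, fit.g(grid), "k-", label="fitted g(r)")
    ax.set_xlabel("distance (m)")
    ax.set_ylabel("detection probability")
    ax.set_title(fit.config.label)
    ax.legend()
    return ax
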