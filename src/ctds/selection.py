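"""AIC ranking, goodness-of-fit gating, and model averaging.

Candidate detection models are screened in two steps: fits that failed to
converge or whose g(r) violates monotonicity are dropped; fits whose
chi-square GOF p-value falls below the study-wide alpha (0.1) are dropped.
Survivors are ranked by AIC. Models within 2 delta-AIC of the best are the
"competing" set; their AIC weights w_i = exp(-delta_i/2)/sum_j exp(-delta_j/2)
drive model averaging of the abundance estimates, with the between-model
spread added to the averaged variance (unconditional variance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .abundance import AbundanceEstimate, lognormal_ci
from .detection import DetectionConfig, DetectionFit

__all__ = [
    "RankedModel",
    "ModelSet",
    "EmptyCompetingSetError",
    "rank_models",
    "model_average",
    "default_model_grid",
]


class EmptyCompetingSetError(RuntimeError):
    """Every candidate fit was excluded; carries per-model diagnostics."""

    def __init__(self, diagnostics: Sequence[tuple[str, str]]):
        self.diagnostics = list(diagnostics)
        detail = "; ".join(f"{label}: {why}" for label, why in self.diagnostics)
        super().__init__(f"no competing detection model ({detail})")


@dataclass
class RankedModel:
    fit: DetectionFit
    delta_aic: float
    weight: float
    gof_p: float
    competing: bool
    excluded_reason: str = ""


@dataclass
class ModelSet:
    models: list[RankedModel]

    @property
    def competing(self) -> list[RankedModel]:
        return [m for m in self.models if m.competing]

    @property
    def best(self) -> RankedModel:
        return self.competing[0]

    @property
    def weights(self) -> list[float]:
        return [m.weight for m in self.competing]


def rank_models(
    fits: Sequence[DetectionFit],
    alpha_gof: float = 0.1,
    delta_max: float = 2.0,
) -> ModelSet:
    """Rank candidate fits by AIC after convergence and GOF screening.

    Exclusion reasons are recorded per model. Delta-AIC is computed over the
    screened set; the competing subset is delta <= ``delta_max``. Ties are
    broken deterministically by (AIC, #parameters, key name, label).
    """
    if not fits:
        raise ValueError("no fits supplied")
    screened: list[tuple[DetectionFit, float, str]] = []
    diagnostics: list[tuple[str, str]] = []
    for f in fits:
        gof_p = f.gof.p_value if (f.gof is not None and f.gof.computable) else float("nan")
        if not f.converged:
            diagnostics.append((f.config.label, "did not converge"))
            screened.append((f, gof_p, "did not converge"))
        elif not f.monotone_ok:
            diagnostics.append((f.config.label, "non-monotone g(r)"))
            screened.append((f, gof_p, "non-monotone g(r)"))
        elif f.gof is not None and f.gof.computable and gof_p < alpha_gof:
            diagnostics.append((f.config.label, f"GOF p = {gof_p:.3f} < {alpha_gof}"))
            screened.append((f, gof_p, f"GOF p < {alpha_gof}"))
        else:
            screened.append((f, gof_p, ""))

    admissible = [(f, p) for f, p, why in screened if not why]
    if not admissible:
        raise EmptyCompetingSetError(diagnostics)

    aic_min = min(f.aic for f, _ in admissible)
    order = sorted(
        screened,
        key=lambda t: (
            bool(t[2]),  # admissible first
            t[0].aic,
            t[0].config.n_params,
            t[0].config.key,
            t[0].config.label,
        ),
    )
    models = []
    for f, gof_p, why in order:
        delta = f.aic - aic_min
        competing = (not why) and delta <= delta_max
        models.append(
            RankedModel(
                fit=f,
                delta_aic=delta if not why else float("nan"),
                weight=0.0,
                gof_p=gof_p,
                competing=competing,
                excluded_reason=why,
            )
        )
    comp = [m for m in models if m.competing]
    raw = np.array([math.exp(-m.delta_aic / 2.0) for m in comp])
    for m, w in zip(comp, raw / raw.sum()):
        m.weight = float(w)
    return ModelSet(models)


def model_average(
    estimates: Sequence[AbundanceEstimate],
    weights: Sequence[float],
    alpha: float = 0.1,
) -> AbundanceEstimate:
    """Model-averaged abundance with unconditional variance.

    N_bar = sum w_i N_i; var = sum w_i (var_i + (N_i - N_bar)^2), so model
    uncertainty is carried into the reported CV and interval. The averaged
    encounter/detection components are the weighted within-model components
    scaled up proportionally to absorb the between-model term, preserving
    cv_total^2 = cv_encounter^2 + cv_detection^2. The df of the average is
    the smallest df among averaged models (conservative).
    """
    if len(estimates) != len(weights):
        raise ValueError("estimates and weights differ in length")
    if abs(sum(weights) - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1")
    strata = {(e.stratum, e.period) for e in estimates}
    if len(strata) > 1:
        raise ValueError(f"cannot average across strata/periods: {sorted(strata)}")
    if len(estimates) == 1:
        return estimates[0]

    w = np.asarray(weights, dtype=float)
    N = np.array([e.N_hat for e in estimates])
    var_i = np.array([e.var_N for e in estimates])
    N_bar = float(w @ N)
    between = float(w @ (N - N_bar) ** 2)
    within = float(w @ var_i)
    var = within + between

    within_e = float(w @ np.array([(e.N_hat * e.cv_encounter) ** 2 for e in estimates]))
    within_p = float(w @ np.array([(e.N_hat * e.cv_detection) ** 2 for e in estimates]))
    cv_total = math.sqrt(var) / N_bar if N_bar > 0 else 0.0
    if within_e + within_p > 0:
        scale = var / (within_e + within_p)
        cv_e = math.sqrt(within_e * scale) / N_bar if N_bar > 0 else 0.0
        cv_p = math.sqrt(within_p * scale) / N_bar if N_bar > 0 else 0.0
    else:
        # no within-model variance: attribute the between-model spread to the
        # encounter (sampling) side, keeping cv_e^2 + cv_p^2 = cv_total^2
        cv_e, cv_p = cv_total, 0.0

    df = min(e.df for e in estimates)
    e0 = estimates[0]
    if cv_total > 0:
        lo, hi = lognormal_ci(N_bar, cv_total, alpha=alpha, df=df)
    else:
        lo = hi = N_bar
    return AbundanceEstimate(
        stratum=e0.stratum,
        period=e0.period,
        n_obs=e0.n_obs,
        D_hat=N_bar / e0.area_km2,
        N_hat=N_bar,
        cv_total=cv_total,
        cv_encounter=cv_e,
        cv_detection=cv_p,
        ci_low=lo,
        ci_high=hi,
        df=df,
        area_km2=e0.area_km2,
        model_label="average[" + ", ".join(e.model_label for e in estimates) + "]",
    )


def default_model_grid(w: float) -> list[DetectionConfig]:
    """Default key x expansion candidate grid.

    Spans the conventional menu — uniform with cosine/simple-polynomial
    adjustments, half-normal alone or with cosine/Hermite adjustments,
    hazard-rate alone or with simple-polynomial adjustments — with 1-2
    adjustment terms where an expansion is present.
    """
    grid: list[DetectionConfig] = []
    for n in (1, 2):
        grid.append(DetectionConfig("uniform", "cosine", n, w))
        grid.append(DetectionConfig("uniform", "simple_polynomial", n, w))
    grid.append(DetectionConfig("half_normal", "none", 0, w))
    for n in (1, 2):
        grid.append(DetectionConfig("half_normal", "cosine", n, w))
        grid.append(DetectionConfig("half_normal", "hermite_polynomial", n, w))
    grid.append(DetectionConfig("hazard_rate", "none", 0, w))
    for n in (1, 2):
        grid.append(DetectionConfig("hazard_rate", "simple_polynomial", n, w))
    return grid
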