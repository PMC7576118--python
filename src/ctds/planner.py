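"""Survey-design precision planning: CV versus number of camera sites.

The encounter-rate variance of a camera-trap point survey scales inversely
with the number of sampling locations K (cameras are the sampling units),
while the detection-probability variance depends on the pooled number of
detections and is treated as K-independent — in practice it is a small
share of the total. Hence

    cv(K)^2 = cv_encounter^2 * (K0 / K) + cv_detection^2,

anchored at the achieved precision cv0 with K0 sites, and the number of
sites needed for a target CV is K_req = round(K0 (cv0/cv_target)^2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["PrecisionPlan", "required_sites", "cv_curve", "precision_plan"]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def required_sites(K0: int, cv0: float, cv_target: float) -> int:
    """Number of sampling locations needed to reach ``cv_target``.

    Assumes variance proportional to 1/K; K_req = round(K0 (cv0/cv_target)^2)
    with half-up rounding. Floored at 2 (a between-site variance needs at
    least two sites), with a warning when the floor binds.
    """
    if K0 <= 0 or cv0 <= 0 or cv_target <= 0:
        raise ValueError("K0, cv0 and cv_target must all be > 0")
    k = _round_half_up(K0 * (cv0 / cv_target) ** 2)
    if k < 2:
        warnings.warn(f"required sites {k} floored at 2")
        k = 2
    return k


def cv_curve(
    K0: int,
    cv_encounter: float,
    cv_detection: float,
    K_range: Sequence[int],
) -> np.ndarray:
    """Predicted total CV at each site count in ``K_range``.

    The encounter component scales as sqrt(K0/K); the detection component is
    held fixed (it depends on the pooled detections used to fit g, not on
    site count). At K = K0 the curve returns the achieved
    sqrt(cv_encounter^2 + cv_detection^2) exactly.
    """
    if cv_encounter < 0 or cv_detection < 0:
        raise ValueError("CV components must be >= 0")
    K = np.asarray(K_range, dtype=float)
    if np.any(K <= 0):
        raise ValueError("site counts must be > 0")
    return np.sqrt(cv_encounter ** 2 * (K0 / K) + cv_detection ** 2)


@dataclass
class PrecisionPlan:
    """A CV-versus-sites tradeoff for survey design."""

    K0: int
    cv0: float
    targets: list[tuple[float, int]]  # (cv_target, K_required)
    curve_K: np.ndarray
    curve_cv: np.ndarray

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        curve = pd.DataFrame({"K": self.curve_K.astype(int), "predicted_cv": self.curve_cv})
        targets = pd.DataFrame(self.targets, columns=["cv_target", "K_required"])
        return curve, targets


def precision_plan(
    K0: int,
    cv_encounter: float,
    cv_detection: float,
    cv_targets: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    K_max: int = 100,
) -> PrecisionPlan:
    """Build a precision plan from achieved CV components at ``K0`` sites."""
    cv0 = math.sqrt(cv_encounter ** 2 + cv_detection ** 2)
    K_range = np.arange(2, K_max + 1)
    curve = cv_curve(K0, cv_encounter, cv_detection, K_range)
    targets = []
    for t in cv_targets:
        if t <= cv_detection:
            # unreachable by adding sites alone; record with a sentinel
            targets.append((t, -1))
        else:
            # invert the curve: K with cv(K) = t
            k_exact = K0 * cv_encounter ** 2 / (t ** 2 - cv_detection ** 2)
            targets.append((t, max(2, _round_half_up(k_exact))))
    return PrecisionPlan(K0=K0, cv0=cv0, targets=targets, curve_K=K_range, curve_cv=curve)
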