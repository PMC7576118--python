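"""End-to-end analysis orchestration and reporting.

load -> censor to diel windows -> effort -> fit the detection-model grid per
stratum -> GOF gate + AIC ranking -> model-average competing models ->
abundance with variance components -> census validation and survey-design
planning. All tabular outputs are CSV with stable column order; a run log
records the config echo, input hashes and seed so every reported number is
recomputable.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab
from . import detection as det
from . import planner as pl
from . import selection as sel
from .observations import (
    CameraDeployment,
    EffortTable,
    ObservationRecord,
    SurveyPeriod,
    build_windows,
    censor_records,
    compute_effort,
    read_deployments,
    read_observations,
)

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "DEFAULT_STRATA",
    "analyze_stratum",
    "run_analysis",
    "compare_to_census",
]

#: Stratum name -> the sex/age categories pooled into it. "adults" pools all
#: animals > 1.5 y including those of undiscernible sex.
DEFAULT_STRATA: dict[str, tuple[str, ...]] = {
    "rams": ("ram",),
    "ewes": ("ewe",),
    "young": ("young",),
    "adults": ("ram", "ewe", "adult_unknown"),
}

_CENSOR_WARN_FRACTION = 0.05


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    observations_path: str | None = None
    deployments_path: str | None = None
    output_dir: str = "ctds_output"
    latitude: float = 32.7
    longitude: float = -108.7
    utc_offset: float = -7.0
    periods: list[SurveyPeriod] = field(default_factory=list)
    strata: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_STRATA))
    trigger_interval_t: float | None = None  # None: per-deployment values
    fov_theta: float | None = None
    truncation_w: float | None = None  # None: max observed distance per stratum
    area_km2: float = 6.2
    alpha: float = 0.1
    gof_bins: int = 5
    min_n: int = 10
    planner_cv_targets: tuple[float, ...] = (0.2, 0.3)
    census: dict = field(default_factory=dict)  # {(stratum, period): N}
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        periods = [
            SurveyPeriod(
                p["label"],
                dt.date.fromisoformat(str(p["start_date"])),
                dt.date.fromisoformat(str(p["end_date"])),
            )
            for p in raw.pop("periods", [])
        ]
        census = {
            (c["stratum"], c["period"]): float(c["N"]) for c in raw.pop("census", [])
        }
        strata = {k: tuple(v) for k, v in raw.pop("strata", DEFAULT_STRATA).items()}
        cfg = cls(periods=periods, census=census, strata=strata, **raw)
        return cfg


@dataclass
class ReportBundle:
    """All outputs of one analysis run."""

    estimates: pd.DataFrame
    model_comparison: pd.DataFrame
    effort: pd.DataFrame
    censoring: pd.DataFrame
    plans: pd.DataFrame
    ratios: pd.DataFrame
    log: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.estimates.to_csv(outdir / "estimates.csv", index=False)
        self.model_comparison.to_csv(outdir / "model_comparison.csv", index=False)
        self.effort.to_csv(outdir / "effort.csv", index=False)
        self.censoring.to_csv(outdir / "censoring.csv", index=False)
        self.plans.to_csv(outdir / "precision_plan.csv", index=False)
        self.ratios.to_csv(outdir / "ratios.csv", index=False)
        (outdir / "run_log.json").write_text(json.dumps(self.log, indent=2, default=str))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def analyze_stratum(
    distances: Sequence[float],
    per_camera_counts: Mapping[str, float],
    effort: EffortTable,
    grid: Sequence[det.DetectionConfig],
    theta: float,
    area_km2: float,
    alpha: float = 0.1,
    gof_bins: int = 5,
    stratum: str = "",
    period: str = "",
) -> tuple[sel.ModelSet | None, ab.AbundanceEstimate | None, str]:
    """Fit the candidate grid, select/average, and estimate one stratum.

    Returns (model set, estimate, skipped_reason); ``skipped_reason`` is a
    non-empty string when the stratum could not be analysed (too few
    observations, no competing model), in which case the other members are
    None — callers report an explicit SKIPPED row, never a silent omission.
    """
    fits: list[det.DetectionFit] = []
    for cfg in grid:
        try:
            fit = det.fit_detection(distances, cfg)
        except det.InsufficientDataError as exc:
            return None, None, f"insufficient data: {exc}"
        except (det.FitFailureError, det.NumericalDegeneracyError):
            continue
        try:
            fit.gof = det.gof_chi2(fit, distances, n_bins=gof_bins)
        except ValueError:
            fit.gof = None
        fits.append(fit)
    if not fits:
        return None, None, "no detection model converged"
    try:
        model_set = sel.rank_models(fits, alpha_gof=alpha)
    except sel.EmptyCompetingSetError as exc:
        return None, None, str(exc)

    per_model = [
        ab.estimate_abundance(
            per_camera_counts,
            effort,
            m.fit,
            theta=theta,
            area_km2=area_km2,
            alpha=alpha,
            stratum=stratum,
            period=period,
        )
        for m in model_set.competing
    ]
    estimate = sel.model_average(per_model, model_set.weights, alpha=alpha)
    return model_set, estimate, ""


def run_analysis(
    config: AnalysisConfig,
    records: Sequence[ObservationRecord] | None = None,
    deployments: Sequence[CameraDeployment] | None = None,
) -> ReportBundle:
    """Run the complete analysis described by ``config``.

    ``records``/``deployments`` may be passed directly (e.g. from the
    simulator); otherwise they are read from the configured paths. The run is
    deterministic given config + inputs.
    """
    import warnings

    log: dict = {
        "config": dataclasses.asdict(config),
        "timestamp": dt.datetime.now().isoformat(),
        "inputs": {},
    }
    if records is None:
        if config.observations_path is None:
            raise ValueError("no observations: set observations_path or pass records")
        records = read_observations(config.observations_path)
        log["inputs"]["observations_sha256"] = _sha256(config.observations_path)
    if deployments is None:
        if config.deployments_path is None:
            raise ValueError("no deployments: set deployments_path or pass deployments")
        deployments = read_deployments(config.deployments_path)
        log["inputs"]["deployments_sha256"] = _sha256(config.deployments_path)
    if not config.periods:
        raise ValueError("config.periods is empty")

    theta = config.fov_theta if config.fov_theta is not None else deployments[0].fov_theta

    est_rows, model_rows, effort_rows, censor_rows, plan_rows, ratio_rows = [], [], [], [], [], []
    estimates_by_key: dict[tuple[str, str], ab.AbundanceEstimate] = {}
    for period in config.periods:
        windows = build_windows(period, config.latitude, config.longitude, config.utc_offset)
        in_period = [r for r in records if period.contains(r.timestamp)]
        retained, frac = censor_records(in_period, windows)
        if frac > _CENSOR_WARN_FRACTION:
            warnings.warn(f"{period.label}: censored fraction {frac:.1%} exceeds 5%")
        censor_rows.append(
            {
                "period": period.label,
                "n_total": len(in_period),
                "n_retained": len(retained),
                "censored_fraction": frac,
            }
        )
        effort = compute_effort(
            deployments, windows, period, t=config.trigger_interval_t, theta=config.fov_theta
        )
        for _, row in effort.table.iterrows():
            effort_rows.append({"period": period.label, **row.to_dict()})

        for stratum, cats in config.strata.items():
            sub = [r for r in retained if r.category in cats]
            distances = [r.distance for r in sub]
            counts: dict[str, float] = {}
            for r in sub:
                counts[r.camera_id] = counts.get(r.camera_id, 0.0) + 1.0
            if len(sub) < config.min_n:
                est_rows.append(
                    _estimate_row(stratum, period.label, len(sub), skipped=f"n = {len(sub)} < {config.min_n}")
                )
                continue
            w = config.truncation_w if config.truncation_w is not None else max(distances)
            grid = sel.default_model_grid(w)
            model_set, estimate, skipped = analyze_stratum(
                distances,
                counts,
                effort,
                grid,
                theta=theta,
                area_km2=config.area_km2,
                alpha=config.alpha,
                gof_bins=config.gof_bins,
                stratum=stratum,
                period=period.label,
            )
            if model_set is not None:
                for m in model_set.models:
                    model_rows.append(
                        {
                            "stratum": stratum,
                            "period": period.label,
                            "model": m.fit.config.label,
                            "n_params": m.fit.config.n_params,
                            "aic": m.fit.aic,
                            "delta_aic": m.delta_aic,
                            "weight": m.weight,
                            "gof_p": m.gof_p,
                            "p_hat": m.fit.p_hat,
                            "competing": m.competing,
                            "excluded_reason": m.excluded_reason,
                        }
                    )
            if skipped:
                est_rows.append(_estimate_row(stratum, period.label, len(sub), skipped=skipped))
                continue
            estimates_by_key[(stratum, period.label)] = estimate
            est_rows.append(_estimate_row(stratum, period.label, len(sub), estimate=estimate))

        key_a = ("adults", period.label)
        if key_a in estimates_by_key:
            e = estimates_by_key[key_a]
            plan = pl.precision_plan(
                K0=len(effort.table),
                cv_encounter=e.cv_encounter,
                cv_detection=e.cv_detection,
                cv_targets=config.planner_cv_targets,
            )
            for tgt, k in plan.targets:
                plan_rows.append(
                    {
                        "period": period.label,
                        "stratum": "adults",
                        "cv_achieved": e.cv_total,
                        "cv_target": tgt,
                        "K_required": k,
                    }
                )
        ewe_key, young_key = ("ewes", period.label), ("young", period.label)
        if ewe_key in estimates_by_key and young_key in estimates_by_key:
            ratio = (
                estimates_by_key[young_key].N_hat / estimates_by_key[ewe_key].N_hat * 100.0
            )
            ratio_rows.append({"period": period.label, "young_per_100_ewes": ratio})

    bundle = ReportBundle(
        estimates=pd.DataFrame(est_rows, columns=_ESTIMATE_COLUMNS),
        model_comparison=pd.DataFrame(
            model_rows,
            columns=[
                "stratum", "period", "model", "n_params", "aic", "delta_aic",
                "weight", "gof_p", "p_hat", "competing", "excluded_reason",
            ],
        ),
        effort=pd.DataFrame(effort_rows),
        censoring=pd.DataFrame(censor_rows),
        plans=pd.DataFrame(
            plan_rows, columns=["period", "stratum", "cv_achieved", "cv_target", "K_required"]
        ),
        ratios=pd.DataFrame(ratio_rows, columns=["period", "young_per_100_ewes"]),
        log=log,
    )
    return bundle


_ESTIMATE_COLUMNS = [
    "stratum", "period", "n_obs", "N_hat", "D_hat", "ci_low", "ci_high",
    "cv", "cv_encounter", "cv_detection", "df", "model", "status",
]


def _estimate_row(
    stratum: str,
    period: str,
    n_obs: int,
    estimate: ab.AbundanceEstimate | None = None,
    skipped: str = "",
) -> dict:
    if estimate is None:
        return {
            "stratum": stratum, "period": period, "n_obs": n_obs,
            "N_hat": np.nan, "D_hat": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            "cv": np.nan, "cv_encounter": np.nan, "cv_detection": np.nan,
            "df": np.nan, "model": "", "status": f"SKIPPED: {skipped}",
        }
    return {
        "stratum": stratum, "period": period, "n_obs": n_obs,
        "N_hat": estimate.N_hat, "D_hat": estimate.D_hat,
        "ci_low": estimate.ci_low, "ci_high": estimate.ci_high,
        "cv": estimate.cv_total, "cv_encounter": estimate.cv_encounter,
        "cv_detection": estimate.cv_detection, "df": estimate.df,
        "model": estimate.model_label, "status": "OK",
    }


def compare_to_census(
    estimates: pd.DataFrame,
    census: Mapping[tuple[str, str], float],
) -> tuple[pd.DataFrame, float]:
    """Validate estimates against known (census) abundances.

    ``estimates`` is the estimates table of a :class:`ReportBundle` (or any
    frame with stratum/period/N_hat/ci_low/ci_high columns). Returns the
    per-row comparison and the mean absolute difference over matched rows.
    Census strata with no matching estimate are listed with status
    UNMATCHED, not dropped.
    """
    rows = []
    diffs = []
    seen = set()
    for _, r in estimates.iterrows():
        key = (r["stratum"], r["period"])
        if key not in census:
            continue
        seen.add(key)
        n_true = census[key]
        if not np.isfinite(r["N_hat"]):
            rows.append({"stratum": key[0], "period": key[1], "census_N": n_true,
                         "N_hat": np.nan, "difference": np.nan, "abs_difference": np.nan,
                         "inside_ci": False, "status": str(r.get("status", ""))})
            continue
        diff = r["N_hat"] - n_true
        inside = bool(r["ci_low"] <= n_true <= r["ci_high"])
        diffs.append(abs(diff))
        rows.append({"stratum": key[0], "period": key[1], "census_N": n_true,
                     "N_hat": r["N_hat"], "difference": diff, "abs_difference": abs(diff),
                     "inside_ci": inside, "status": "OK"})
    for key, n_true in census.items():
        if key not in seen:
            rows.append({"stratum": key[0], "period": key[1], "census_N": n_true,
                         "N_hat": np.nan, "difference": np.nan, "abs_difference": np.nan,
                         "inside_ci": False, "status": "UNMATCHED"})
    table = pd.DataFrame(rows)
    mean_abs = float(np.mean(diffs)) if diffs else float("nan")
    return table, mean_abs
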