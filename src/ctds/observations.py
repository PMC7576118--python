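"""Observation data model, file I/O, availability windows, censoring and effort.

A camera-trap distance sampling survey is described by two tables:
observation records (one row per classified animal in an image, with its
radial distance from the camera) and camera deployments (location,
operational intervals, trigger interval t and field-of-view angle theta).
Survey effort is the number of trigger opportunities per camera — operating
seconds intersected with the diel availability window, divided by t — scaled
by the viewshed fraction theta/360.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .solar import sunrise_sunset

__all__ = [
    "CATEGORIES",
    "ObservationRecord",
    "CameraDeployment",
    "AvailabilityWindow",
    "SurveyPeriod",
    "EffortTable",
    "FALL",
    "SPRING",
    "SchemaError",
    "RowValidationError",
    "MissingWindowError",
    "read_observations",
    "write_observations",
    "read_deployments",
    "write_deployments",
    "solar_window",
    "build_windows",
    "censor_records",
    "compute_effort",
]

#: Closed vocabulary of sex/age classes. "adult_unknown" is an adult-sized
#: animal whose sex could not be discerned; "unknown" is unclassifiable
#: imagery and is excluded from category-specific analyses but counted in
#: totals.
CATEGORIES = ("ram", "ewe", "young", "adult_unknown", "unknown")

#: Offsets defining the diel availability window relative to sunrise/sunset.
SUNRISE_OFFSET_S = -3600.0  # window opens 1 h before sunrise
SUNSET_OFFSET_S = 7200.0  # window closes 2 h after sunset


class SchemaError(ValueError):
    """An input table is missing required columns."""


class RowValidationError(ValueError):
    """One or more rows failed validation; carries (row index, message) pairs."""

    def __init__(self, failures: Sequence[tuple[int, str]]):
        self.failures = list(failures)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.failures[:10])
        extra = "" if len(self.failures) <= 10 else f" (+{len(self.failures) - 10} more)"
        super().__init__(f"{len(self.failures)} invalid row(s): {lines}{extra}")


class MissingWindowError(KeyError):
    """A record's date has no availability window."""


@dataclass(frozen=True)
class ObservationRecord:
    """One detected animal in one image."""

    camera_id: str
    timestamp: dt.datetime
    species: str
    category: str
    distance: float  # radial distance from camera, metres

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}; expected one of {CATEGORIES}")
        if self.distance < 0:
            raise ValueError(f"negative distance {self.distance}")


@dataclass
class CameraDeployment:
    """A camera's location, operational history and sampling geometry."""

    camera_id: str
    latitude: float
    longitude: float
    operational_intervals: list[tuple[dt.datetime, dt.datetime]]
    trigger_interval_t: float = 15.0  # seconds between trigger opportunities
    fov_theta: float = 50.0  # field-of-view angle, degrees

    def __post_init__(self) -> None:
        if self.trigger_interval_t <= 0:
            raise ValueError("trigger_interval_t must be > 0")
        if not 0 < self.fov_theta <= 360:
            raise ValueError("fov_theta must be in (0, 360]")
        ivals = sorted(self.operational_intervals)
        for (s0, e0), (s1, _) in zip(ivals, ivals[1:]):
            if e0 > s1:
                raise ValueError(f"overlapping operational intervals for camera {self.camera_id}")
        for s, e in ivals:
            if e <= s:
                raise ValueError(f"empty operational interval for camera {self.camera_id}")
        self.operational_intervals = ivals


@dataclass(frozen=True)
class AvailabilityWindow:
    """Diel window within which animals are considered available for detection."""

    date: dt.date
    window_start: dt.datetime
    window_end: dt.datetime

    def __post_init__(self) -> None:
        if self.window_start >= self.window_end:
            raise ValueError("window_start must precede window_end")

    def contains(self, ts: dt.datetime) -> bool:
        return self.window_start <= ts <= self.window_end


@dataclass(frozen=True)
class SurveyPeriod:
    """A labelled analysis period; both end dates are inclusive."""

    label: str
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError("start_date after end_date")

    def dates(self) -> list[dt.date]:
        n = (self.end_date - self.start_date).days + 1
        return [self.start_date + dt.timedelta(days=i) for i in range(n)]

    def contains(self, ts: dt.datetime) -> bool:
        return self.start_date <= ts.date() <= self.end_date


FALL = SurveyPeriod("fall", dt.date(2017, 10, 1), dt.date(2018, 1, 31))
SPRING = SurveyPeriod("spring", dt.date(2018, 3, 1), dt.date(2018, 5, 1))


@dataclass
class EffortTable:
    """Per-camera effort: available seconds, trigger opportunities, effective effort.

    ``snapshots`` is real-valued (available_seconds / t): effort is a rate
    denominator, not an event count. ``effective_effort`` is snapshots scaled
    by the viewshed fraction theta/360.
    """

    table: pd.DataFrame  # columns: camera_id, available_seconds, snapshots, effective_effort

    COLUMNS = ("camera_id", "available_seconds", "snapshots", "effective_effort")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise SchemaError(f"effort table missing columns {sorted(missing)}")
        if (self.table[list(self.COLUMNS[1:])] < 0).any().any():
            raise ValueError("effort entries must be >= 0")

    @property
    def camera_ids(self) -> list[str]:
        return list(self.table["camera_id"])

    @property
    def total_snapshots(self) -> float:
        return float(self.table["snapshots"].sum())

    @property
    def total_effective_effort(self) -> float:
        return float(self.table["effective_effort"].sum())

    def effective_by_camera(self) -> dict[str, float]:
        return dict(zip(self.table["camera_id"], self.table["effective_effort"]))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# file I/O

DEFAULT_SCHEMA: Mapping[str, str] = {
    "camera_id": "camera_id",
    "timestamp": "timestamp",
    "species": "species",
    "category": "category",
    "distance": "distance",
}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def read_observations(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    max_distance: float | None = None,
) -> list[ObservationRecord]:
    """Read observation records from a CSV or spreadsheet.

    ``schema`` maps record fields to column names in the file. Rows failing
    validation (unparsable timestamp, negative or non-numeric distance,
    unknown category) are reported collectively via :class:`RowValidationError`
    with their row indices — never silently dropped.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    df = _read_table(path)
    missing = [col for col in schema.values() if col not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; have {list(df.columns)}")

    failures: list[tuple[int, str]] = []
    records: list[ObservationRecord] = []
    ts = pd.to_datetime(df[schema["timestamp"]], errors="coerce")
    dist = pd.to_numeric(df[schema["distance"]], errors="coerce")
    for i in range(len(df)):
        row = df.iloc[i]
        msgs = []
        if pd.isna(ts.iloc[i]):
            msgs.append(f"unparsable timestamp {row[schema['timestamp']]!r}")
        if pd.isna(dist.iloc[i]):
            msgs.append(f"non-numeric distance {row[schema['distance']]!r}")
        elif dist.iloc[i] < 0:
            msgs.append(f"negative distance {dist.iloc[i]}")
        elif max_distance is not None and dist.iloc[i] > max_distance:
            msgs.append(f"distance {dist.iloc[i]} exceeds maximum {max_distance}")
        category = str(row[schema["category"]])
        if category not in CATEGORIES:
            msgs.append(f"unknown category {category!r}")
        if msgs:
            failures.append((i, "; ".join(msgs)))
            continue
        records.append(
            ObservationRecord(
                camera_id=str(row[schema["camera_id"]]),
                timestamp=ts.iloc[i].to_pydatetime(),
                species=str(row[schema["species"]]),
                category=category,
                distance=float(dist.iloc[i]),
            )
        )
    if failures:
        raise RowValidationError(failures)
    return records


def write_observations(records: Iterable[ObservationRecord], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    df["timestamp"] = df["timestamp"].map(lambda t: t.isoformat(sep=" "))
    df.to_csv(path, index=False)


def read_deployments(path: str | Path) -> list[CameraDeployment]:
    """Read deployments from CSV: one row per operational interval.

    Columns: camera_id, latitude, longitude, start, end,
    trigger_interval_t (optional), fov_theta (optional). Gaps from camera
    failures are simply absent intervals; nothing is imputed.
    """
    df = _read_table(path)
    required = {"camera_id", "latitude", "longitude", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for cam, grp in df.groupby("camera_id", sort=True):
        intervals = [
            (pd.to_datetime(s).to_pydatetime(), pd.to_datetime(e).to_pydatetime())
            for s, e in zip(grp["start"], grp["end"])
        ]
        first = grp.iloc[0]
        out.append(
            CameraDeployment(
                camera_id=str(cam),
                latitude=float(first["latitude"]),
                longitude=float(first["longitude"]),
                operational_intervals=intervals,
                trigger_interval_t=float(first.get("trigger_interval_t", 15.0)),
                fov_theta=float(first.get("fov_theta", 50.0)),
            )
        )
    return out


def write_deployments(deployments: Iterable[CameraDeployment], path: str | Path) -> None:
    rows = []
    for d in deployments:
        for s, e in d.operational_intervals:
            rows.append(
                {
                    "camera_id": d.camera_id,
                    "latitude": d.latitude,
                    "longitude": d.longitude,
                    "start": s.isoformat(sep=" "),
                    "end": e.isoformat(sep=" "),
                    "trigger_interval_t": d.trigger_interval_t,
                    "fov_theta": d.fov_theta,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# availability windows and censoring


def solar_window(
    date: dt.date, latitude: float, longitude: float, utc_offset: float
) -> AvailabilityWindow:
    """Diel availability window for one day: sunrise − 1 h to sunset + 2 h."""
    sunrise, sunset = sunrise_sunset(date, latitude, longitude, utc_offset)
    return AvailabilityWindow(
        date=date,
        window_start=sunrise + dt.timedelta(seconds=SUNRISE_OFFSET_S),
        window_end=sunset + dt.timedelta(seconds=SUNSET_OFFSET_S),
    )


def build_windows(
    period: SurveyPeriod, latitude: float, longitude: float, utc_offset: float
) -> dict[dt.date, AvailabilityWindow]:
    """Daily availability windows for every date of a survey period."""
    return {d: solar_window(d, latitude, longitude, utc_offset) for d in period.dates()}


def censor_records(
    records: Sequence[ObservationRecord],
    windows: Mapping[dt.date, AvailabilityWindow],
) -> tuple[list[ObservationRecord], float]:
    """Keep records whose timestamp falls inside the day's availability window.

    Returns (retained records, censored fraction). A record dated outside the
    window map raises :class:`MissingWindowError` — availability must be
    defined wherever data exist.
    """
    retained = []
    for r in records:
        day = r.timestamp.date()
        if day not in windows:
            raise MissingWindowError(f"no availability window for {day} (camera {r.camera_id})")
        if windows[day].contains(r.timestamp):
            retained.append(r)
    frac = 0.0 if not records else 1.0 - len(retained) / len(records)
    return retained, frac


def _overlap_seconds(a0: dt.datetime, a1: dt.datetime, b0: dt.datetime, b1: dt.datetime) -> float:
    lo, hi = max(a0, b0), min(a1, b1)
    return max(0.0, (hi - lo).total_seconds())


def compute_effort(
    deployments: Sequence[CameraDeployment],
    windows: Mapping[dt.date, AvailabilityWindow],
    period: SurveyPeriod,
    t: float | None = None,
    theta: float | None = None,
) -> EffortTable:
    """Per-camera survey effort over a period.

    available_seconds = sum over days of |operational ∩ availability window|
    restricted to the period; snapshots = available_seconds / t (trigger
    opportunities, real-valued); effective_effort = snapshots * theta/360.

    ``t`` and ``theta`` override per-deployment values when given. If no
    camera accumulates effort a zero-effort warning is issued, not an error.
    """
    import warnings

    days = [d for d in period.dates() if d in windows]
    rows = []
    for dep in deployments:
        t_cam = t if t is not None else dep.trigger_interval_t
        theta_cam = theta if theta is not None else dep.fov_theta
        if t_cam <= 0:
            raise ValueError("t must be > 0")
        avail = 0.0
        for day in days:
            w = windows[day]
            for s, e in dep.operational_intervals:
                avail += _overlap_seconds(s, e, w.window_start, w.window_end)
        snaps = avail / t_cam
        rows.append(
            {
                "camera_id": dep.camera_id,
                "available_seconds": avail,
                "snapshots": snaps,
                "effective_effort": snaps * theta_cam / 360.0,
            }
        )
    table = pd.DataFrame(rows, columns=list(EffortTable.COLUMNS))
    if len(table) and float(table["available_seconds"].sum()) == 0.0:
        warnings.warn("zero effort: no operational time intersects availability windows")
    return EffortTable(table)
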