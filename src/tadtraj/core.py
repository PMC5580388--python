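"""Core trajectory handling for frog telemetry.

Telemetry fixes are timestamped planar positions (projected meters) of
individually identified frogs, recorded every 30-60 min during daylight
(07:00-19:00 by default).  A full track is split into two phases:

* ``TT`` (tadpole transport): from the first encounter point to the last
  tadpole deposition site, and
* ``HT`` (homing): from the last deposition site back to the home territory.

This module provides the data model (:class:`Trajectory`, :class:`Territory`,
:class:`DaylightWindow`), CSV I/O, phase segmentation, and the distance /
night-excluded duration / speed accounting used throughout the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import time, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "DaylightWindow",
    "Territory",
    "Trajectory",
    "read_fixes",
    "write_fixes",
    "read_territories",
    "territory_center",
    "territory_centers",
    "segment_phases",
    "path_length",
    "interpolate_start",
    "active_duration",
    "elapsed_active_hours",
    "interval_speeds",
    "mean_speed",
    "step_speeds",
]

BEHAVIORS = ("territorial", "transport", "other", "unknown")
MAX_TADPOLES = 25  # largest load ever recorded for this species

FIX_COLUMNS = ("frog_id", "timestamp", "x_m", "y_m", "tadpoles", "behavior")


class SchemaError(ValueError):
    """An input file does not have the required columns."""


class ValidationError(ValueError):
    """Input data violate a documented invariant."""


@dataclass(frozen=True)
class DaylightWindow:
    """Daily tracking window; frogs are strictly diurnal and were only
    followed between ``day_start`` and ``day_end`` local time."""

    day_start: time = time(7, 0)
    day_end: time = time(19, 0)

    def __post_init__(self) -> None:
        if self.day_start >= self.day_end:
            raise ValidationError("day_start must precede day_end")

    @property
    def day_hours(self) -> float:
        return (
            self.day_end.hour * 60 + self.day_end.minute
            - self.day_start.hour * 60 - self.day_start.minute
        ) / 60.0

    @property
    def night_hours(self) -> float:
        """Hours subtracted per night spanned by a track (default 12)."""
        return 24.0 - self.day_hours


@dataclass
class Territory:
    """Home territory of one male, summarised by the centroid of the
    capture locations at which he displayed territorial behavior."""

    frog_id: str
    center: np.ndarray
    n_captures: int

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        if self.n_captures < 1:
            raise ValidationError("territory requires at least one capture")
        if not np.all(np.isfinite(self.center)):
            raise ValidationError("territory center must be finite")


@dataclass
class Trajectory:
    """An ordered fix sequence for one frog in one movement phase.

    ``waypoints`` define the ideal route: for a TT the first fix followed by
    each visited deposition site in visit order (the last waypoint is the
    last deposition site); for a HT the last deposition site followed by the
    territory center.  ``waypoint_times`` holds the arrival time at each
    waypoint (``None`` for waypoints that are not tied to a fix, such as the
    start point or the territory center).
    """

    frog_id: str
    phase: str  # "TT", "HT" or "full"
    fixes: pd.DataFrame
    waypoints: np.ndarray | None = None
    waypoint_times: list | None = None
    interpolated_start_m: float | None = None
    complete: bool = True

    def __post_init__(self) -> None:
        if self.phase not in ("TT", "HT", "full"):
            raise ValidationError(f"unknown phase {self.phase!r}")
        if len(self.fixes) < 2:
            raise ValidationError("a trajectory needs at least 2 fixes")
        if self.waypoints is not None:
            self.waypoints = np.asarray(self.waypoints, dtype=float).reshape(-1, 2)
            if len(self.waypoints) < 2:
                raise ValidationError("waypoint chain needs at least 2 points")
            if self.waypoint_times is None:
                self.waypoint_times = [None] * len(self.waypoints)
        elif self.phase != "full":
            raise ValidationError("TT/HT trajectories require waypoints")

    @property
    def xy(self) -> np.ndarray:
        return self.fixes[["x_m", "y_m"]].to_numpy(dtype=float)

    @property
    def times(self) -> pd.Series:
        return self.fixes["timestamp"]

    @property
    def n_locations(self) -> int:
        return len(self.fixes)


# ---------------------------------------------------------------------------
# I/O


def _looks_like_lonlat(x: np.ndarray, y: np.ndarray) -> bool:
    # degree coordinates sit inside the lon/lat bounds AND span a tiny range
    # (a tracked frog covers meters, i.e. ~1e-3 degrees, never whole degrees)
    in_bounds = bool(np.all(np.abs(x) <= 180) and np.all(np.abs(y) <= 90))
    tiny_extent = bool(np.ptp(x) < 1.0 and np.ptp(y) < 1.0)
    return in_bounds and tiny_extent


def _validate_fix_frame(df: pd.DataFrame) -> None:
    x = df["x_m"].to_numpy(dtype=float)
    y = df["y_m"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite coordinates in fix table")
    if len(df) and _looks_like_lonlat(x, y):
        raise ValidationError(
            "coordinates look like longitude/latitude degrees; project to a "
            "planar CRS (meters) before reading"
        )
    known = df["tadpoles"].dropna()
    if len(known) and (known.lt(0).any() or known.gt(MAX_TADPOLES).any()):
        raise ValidationError(
            f"tadpole counts must be in [0, {MAX_TADPOLES}] when known"
        )
    for frog, grp in df.groupby("frog_id", sort=False):
        t = grp["timestamp"]
        bad = np.flatnonzero(t.diff().dt.total_seconds().to_numpy() <= 0)
        if bad.size:
            rows = grp.index[bad].tolist()
            raise ValidationError(
                f"non-increasing timestamps for frog {frog!r} at rows {rows}"
            )


def read_fixes(
    path,
    schema: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> dict[str, pd.DataFrame]:
    """Read a fix CSV and return one validated DataFrame per frog.

    ``schema`` maps the standard column names (``frog_id``, ``timestamp``,
    ``x_m``, ``y_m``, ``tadpoles``, ``behavior``) to the column names used in
    the file.  The two optional columns may be absent; unknown values are
    kept as missing (NaN / ``"unknown"``), never coerced to zero.
    """
    schema = dict(schema or {})
    try:
        raw = pd.read_csv(path, delimiter=delimiter)
    except OSError:
        raise
    rename = {schema.get(std, std): std for std in FIX_COLUMNS}
    raw = raw.rename(columns=rename)
    for col in ("frog_id", "timestamp", "x_m", "y_m"):
        if col not in raw.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    df = pd.DataFrame(
        {
            "frog_id": raw["frog_id"].astype(str),
            "timestamp": pd.to_datetime(raw["timestamp"]),
            "x_m": raw["x_m"].astype(float),
            "y_m": raw["y_m"].astype(float),
        }
    )
    if "tadpoles" in raw.columns:
        df["tadpoles"] = pd.to_numeric(raw["tadpoles"], errors="coerce")
    else:
        df["tadpoles"] = np.nan
    if "behavior" in raw.columns:
        beh = raw["behavior"].astype("string").str.strip().str.lower()
        beh = beh.where(beh.isin(BEHAVIORS), other=pd.NA).fillna("unknown")
        df["behavior"] = beh.astype(str)
    else:
        df["behavior"] = "unknown"
    df = df.sort_values(["frog_id", "timestamp"], kind="stable").reset_index(drop=True)
    _validate_fix_frame(df)
    return {str(frog): grp.reset_index(drop=True) for frog, grp in df.groupby("frog_id", sort=False)}


def write_fixes(fixes, path, delimiter: str = ",") -> None:
    """Write fixes (a DataFrame or a frog->DataFrame mapping) to CSV in the
    dialect :func:`read_fixes` reads back."""
    if isinstance(fixes, Mapping):
        df = pd.concat(fixes.values(), ignore_index=True)
    else:
        df = fixes.copy()
    out = df[list(FIX_COLUMNS)].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out["tadpoles"] = out["tadpoles"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    out.to_csv(path, index=False, sep=delimiter)


def read_territories(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a territory-capture CSV: frog_id, timestamp, x_m, y_m,
    territorial (0/1)."""
    raw = pd.read_csv(path, delimiter=delimiter)
    for col in ("frog_id", "x_m", "y_m", "territorial"):
        if col not in raw.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    df = raw.copy()
    df["frog_id"] = df["frog_id"].astype(str)
    df["territorial"] = df["territorial"].astype(int)
    return df


# ---------------------------------------------------------------------------
# Territory center


def territory_center(points, territorial, frog_id: str = "") -> Territory:
    """Arithmetic centroid of the capture points flagged as territorial
    behavior (calling, courtship, aggression); non-territorial captures are
    ignored."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    flags = np.asarray(territorial, dtype=bool)
    if flags.shape[0] != pts.shape[0]:
        raise ValidationError("points and flags must have equal length")
    used = pts[flags]
    if used.shape[0] == 0:
        raise ValidationError("no territorial captures")
    return Territory(frog_id=frog_id, center=used.mean(axis=0), n_captures=int(used.shape[0]))


def territory_centers(captures: pd.DataFrame) -> dict[str, Territory]:
    """Territory centers for every frog in a territory-capture table."""
    out: dict[str, Territory] = {}
    for frog, grp in captures.groupby("frog_id", sort=False):
        out[str(frog)] = territory_center(
            grp[["x_m", "y_m"]].to_numpy(), grp["territorial"].to_numpy(), str(frog)
        )
    return out


# ---------------------------------------------------------------------------
# Distance / duration / speed accounting


def _as_xy(traj) -> np.ndarray:
    if isinstance(traj, Trajectory):
        return traj.xy
    return np.asarray(traj, dtype=float).reshape(-1, 2)


def path_length(traj) -> float:
    """Total path distance: sum of Euclidean fix-to-fix segment lengths."""
    xy = _as_xy(traj)
    if len(xy) < 2:
        raise ValidationError("path_length needs at least 2 fixes")
    return float(np.hypot(*np.diff(xy, axis=0).T).sum())


def interpolate_start(territory: Territory, first_fix) -> float:
    """Straight-line chord from the territory center to the first encounter
    location: a minimum-distance estimate of the untracked start of a
    transport (never exceeds the true path)."""
    p = np.asarray(first_fix, dtype=float).reshape(2)
    return float(np.hypot(*(p - territory.center)))


def _clamp_times(ts: pd.Series, window: DaylightWindow) -> pd.Series:
    """Clamp any fix logged outside the daylight window to the window edge.

    The field protocol precludes true night fixes, so out-of-window stamps
    are treated as clock drift, warned about, and clamped."""
    ts = pd.to_datetime(ts)
    lo = ts.dt.normalize() + pd.Timedelta(hours=window.day_start.hour, minutes=window.day_start.minute)
    hi = ts.dt.normalize() + pd.Timedelta(hours=window.day_end.hour, minutes=window.day_end.minute)
    clamped = ts.clip(lower=lo, upper=hi)
    n_out = int((clamped != ts).sum())
    if n_out:
        warnings.warn(
            f"{n_out} fix(es) outside the {window.day_start:%H:%M}-"
            f"{window.day_end:%H:%M} window clamped to the window edge",
            stacklevel=3,
        )
    return clamped


def elapsed_active_hours(t0, t1, window: DaylightWindow = DaylightWindow()) -> float:
    """Elapsed hours between two daylight timestamps with nights excluded:
    (t1 - t0) minus ``night_hours`` per night spanned."""
    t0 = pd.Timestamp(t0)
    t1 = pd.Timestamp(t1)
    if t1 < t0:
        raise ValidationError("end time precedes start time")
    nights = (t1.normalize() - t0.normalize()).days
    hours = (t1 - t0).total_seconds() / 3600.0 - window.night_hours * nights
    return max(hours, 0.0)


def active_duration(traj, window: DaylightWindow = DaylightWindow()) -> float:
    """Night-excluded duration of a trajectory in hours."""
    ts = traj.times if isinstance(traj, Trajectory) else pd.Series(pd.to_datetime(traj))
    ts = _clamp_times(ts, window)
    return elapsed_active_hours(ts.iloc[0], ts.iloc[-1], window)


def mean_speed(traj: Trajectory, window: DaylightWindow = DaylightWindow()) -> float:
    """Average speed in m/h: path length over night-excluded duration."""
    hours = active_duration(traj, window)
    if hours <= 0:
        raise ValidationError("zero active duration")
    return path_length(traj) / hours


def step_speeds(traj: Trajectory, window: DaylightWindow = DaylightWindow()) -> np.ndarray:
    """Speed (m/h) of every consecutive fix pair, night-excluded for steps
    spanning a night."""
    xy = traj.xy
    if len(xy) < 2:
        raise ValidationError("step_speeds needs at least 2 fixes")
    ts = _clamp_times(traj.times, window).reset_index(drop=True)
    dist = np.hypot(*np.diff(xy, axis=0).T)
    hours = np.array(
        [elapsed_active_hours(ts[i], ts[i + 1], window) for i in range(len(ts) - 1)]
    )
    if np.any(hours <= 0):
        raise ValidationError("duplicate or zero-duration steps")
    return dist / hours


def interval_speeds(
    fixes: pd.DataFrame,
    window: DaylightWindow = DaylightWindow(),
    interval_hours: float = 3.0,
) -> pd.DataFrame:
    """Distance moved per within-day activity interval, as speed in m/h.

    The tracking day is split into equal intervals (default four 3-h blocks,
    07-10/10-13/13-16/16-19); each step's distance is apportioned to the
    intervals it overlaps in proportion to time.  Returns one row per
    (frog, date, interval) actually covered by the track, with the speed,
    the covered hours, and whether tadpoles were carried at the interval's
    first contributing fix.
    """
    fixes = fixes.reset_index(drop=True)
    ts = _clamp_times(fixes["timestamp"], window)
    xy = fixes[["x_m", "y_m"]].to_numpy(dtype=float)
    day0 = window.day_start.hour + window.day_start.minute / 60.0
    acc: dict[tuple, dict] = {}
    for i in range(len(fixes) - 1):
        t0, t1 = ts[i], ts[i + 1]
        hours = elapsed_active_hours(t0, t1, window)
        if hours <= 0:
            continue
        dist = float(np.hypot(*(xy[i + 1] - xy[i])))
        day = t0.normalize()
        while day <= t1.normalize():
            k = 0
            while day0 + (k + 1) * interval_hours <= 24.0 and k * interval_hours < window.day_hours:
                lo = day + pd.Timedelta(hours=day0 + k * interval_hours)
                hi = min(day + pd.Timedelta(hours=day0 + (k + 1) * interval_hours),
                         day + pd.Timedelta(hours=day0 + window.day_hours))
                ov = (min(t1, hi) - max(t0, lo)).total_seconds() / 3600.0
                if ov > 0:
                    key = (str(fixes["frog_id"].iloc[0]), day.date().isoformat(),
                           day0 + k * interval_hours)
                    slot = acc.setdefault(
                        key,
                        {"distance_m": 0.0, "hours": 0.0,
                         "tadpoles_present": float(
                             fixes["tadpoles"].iloc[i] > 0
                         ) if pd.notna(fixes["tadpoles"].iloc[i]) else np.nan},
                    )
                    slot["distance_m"] += dist * ov / hours
                    slot["hours"] += ov
                k += 1
            day += pd.Timedelta(days=1)
    rows = [
        {"frog_id": f, "date": d, "interval_start_h": h, **v,
         "speed_m_per_h": v["distance_m"] / v["hours"]}
        for (f, d, h), v in sorted(acc.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["frog_id", "date", "interval_start_h", "distance_m", "hours",
                 "tadpoles_present", "speed_m_per_h"],
    )


# ---------------------------------------------------------------------------
# Phase segmentation


def segment_phases(
    fixes: pd.DataFrame,
    visits: Sequence,
    territory: Territory,
    r_home: float = 7.0,
) -> tuple[Trajectory, Trajectory]:
    """Split a full track into the transport (TT) and homing (HT) phases.

    TT runs from the first fix through the last fix of the visit at which the
    last tadpole deposition occurred; HT runs from that same fix (shared, so
    distances partition exactly) through the first fix within ``r_home``
    meters of the territory center.  If the frog never returns within the
    track the HT is marked incomplete rather than silently truncated.

    ``visits`` are :class:`tadtraj.pools.VisitEvent` records for this track.
    """
    fixes = fixes.reset_index(drop=True)
    frog_id = str(fixes["frog_id"].iloc[0])
    depositions = [v for v in visits if v.deposition is True]
    if not depositions:
        raise ValidationError("no deposition event in this track")
    last_dep = max(depositions, key=lambda v: v.t_arrive)
    ts = fixes["timestamp"]
    in_visit = np.flatnonzero((ts >= last_dep.t_arrive) & (ts <= last_dep.t_depart))
    if in_visit.size == 0:
        raise ValidationError("deposition visit does not overlap the fix sequence")
    split = int(in_visit[-1])

    # TT waypoints: first fix, then each visited pool (in visit order) up to
    # and including the last deposition site.
    tt_fixes = fixes.iloc[: split + 1].reset_index(drop=True)
    tt_visits = sorted(
        (v for v in visits if v.t_arrive <= last_dep.t_arrive),
        key=lambda v: v.t_arrive,
    )
    waypoints = [tt_fixes[["x_m", "y_m"]].iloc[0].to_numpy(dtype=float)]
    times: list = [None]
    for v in tt_visits:
        pt = np.array([v.x, v.y], dtype=float)
        if np.allclose(pt, waypoints[-1]):
            continue
        waypoints.append(pt)
        times.append(v.t_arrive)
    tt = Trajectory(
        frog_id=frog_id,
        phase="TT",
        fixes=tt_fixes,
        waypoints=np.array(waypoints),
        waypoint_times=times,
        interpolated_start_m=interpolate_start(territory, waypoints[0]),
    )

    rest = fixes.iloc[split:].reset_index(drop=True)
    d_home = np.hypot(
        rest["x_m"].to_numpy(dtype=float) - territory.center[0],
        rest["y_m"].to_numpy(dtype=float) - territory.center[1],
    )
    back = np.flatnonzero(d_home[1:] <= r_home)
    complete = back.size > 0
    end = int(back[0]) + 1 if complete else len(rest) - 1
    ht_fixes = rest.iloc[: end + 1].reset_index(drop=True)
    ht = Trajectory(
        frog_id=frog_id,
        phase="HT",
        fixes=ht_fixes,
        waypoints=np.array([[last_dep.x, last_dep.y], territory.center]),
        waypoint_times=[last_dep.t_arrive, None],
        complete=complete,
    )
    return tt, ht
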