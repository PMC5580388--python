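"""Goal-directed movement precision statistics.

Three per-trajectory statistics quantify how precisely a frog moves toward
its goals (the upcoming deposition pools during transport, the home territory
during homing):

* the straightness coefficient (SC): ideal chord distance through the ordered
  goals divided by the realized path length, in (0, 1];
* the mean absolute angular deviation between the ideal direction (fix ->
  current goal) and the realized direction (fix -> next fix), in [0, 180]
  degrees;
* the mean perpendicular deviation of fixes from the ideal straight path,
  in meters.

Directionality is tested with the Rayleigh test of circular uniformity
(statistic Z = n * rbar^2 with the standard series p approximation).
Trajectories with three or fewer locations are excluded from directionality
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Trajectory, ValidationError, path_length

__all__ = [
    "RayleighResult",
    "PrecisionSummary",
    "step_headings",
    "bearing",
    "wrap_signed",
    "straightness_coefficient",
    "assign_goals",
    "angular_deviation",
    "goal_relative_angles",
    "perpendicular_deviation",
    "rayleigh_test",
    "precision_summary",
]

MIN_LOCATIONS = 4  # "more than three locations" admission rule


@dataclass(frozen=True)
class RayleighResult:
    n: int
    rbar: float
    z: float
    p: float


@dataclass
class PrecisionSummary:
    frog_id: str
    phase: str
    n_locations: int
    sc: float
    mean_ang_dev_deg: float
    mean_perp_dev_m: float
    rayleigh: RayleighResult | None = None


def bearing(origin, target) -> np.ndarray:
    """Absolute angle(s) in degrees from origin(s) to target(s), measured
    counter-clockwise from east in [0, 360)."""
    o = np.asarray(origin, dtype=float).reshape(-1, 2)
    t = np.asarray(target, dtype=float).reshape(-1, 2)
    d = t - o
    ang = np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 360.0
    return ang if ang.size > 1 else ang


def wrap_signed(deg) -> np.ndarray:
    """Wrap angles (degrees) to [-180, 180)."""
    return (np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0


def step_headings(traj) -> np.ndarray:
    """Absolute heading per step (east = 0 deg, counter-clockwise); steps of
    zero length are omitted."""
    xy = traj.xy if isinstance(traj, Trajectory) else np.asarray(traj, float).reshape(-1, 2)
    if len(xy) < 2:
        raise ValidationError("step_headings needs at least 2 fixes")
    d = np.diff(xy, axis=0)
    moved = np.hypot(d[:, 0], d[:, 1]) > 0
    if not moved.any():
        raise ValidationError("no movement")
    return np.degrees(np.arctan2(d[moved, 1], d[moved, 0])) % 360.0


def straightness_coefficient(traj: Trajectory) -> float:
    """Ratio of the ideal route length (piecewise chord through the ordered
    waypoints) to the realized path length.

    A value marginally above 1 can arise from telemetry noise on a
    near-perfectly straight path; such values are clipped to 1 (with a
    warning when the excess exceeds numerical tolerance).
    """
    if traj.waypoints is None or len(traj.waypoints) < 2:
        raise ValidationError("straightness needs at least 2 waypoints")
    total = path_length(traj)
    if total <= 0:
        raise ValidationError("zero path length")
    chord = float(np.hypot(*np.diff(traj.waypoints, axis=0).T).sum())
    sc = chord / total
    if sc > 1.0:
        if sc > 1.0 + 1e-9:
            warnings.warn(
                "straightness > 1 (measurement noise); clipping to 1",
                stacklevel=2,
            )
        sc = 1.0
    return sc


def assign_goals(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-fix goal and ideal chord segment.

    Each fix is assigned the next waypoint not yet reached at that fix's time
    (chronological attribution: during a multi-pool transport the goal is the
    deposition site visited next).  Returns ``(goals, segments)`` where
    ``goals`` is (n, 2) and ``segments`` is (n, 2, 2) holding the waypoint
    pair whose chord is the ideal path for that fix.  Fixes after the last
    waypoint arrival keep the final segment.
    """
    if traj.waypoints is None:
        raise ValidationError("trajectory has no waypoints")
    w = traj.waypoints
    wt = traj.waypoint_times
    n = traj.n_locations
    goals = np.empty((n, 2))
    segs = np.empty((n, 2, 2))
    ts = traj.times.reset_index(drop=True)
    for i in range(n):
        g = len(w) - 1
        for j in range(1, len(w)):
            if wt[j] is None or ts[i] < wt[j]:
                g = j
                break
        goals[i] = w[g]
        segs[i, 0] = w[g - 1]
        segs[i, 1] = w[g]
    return goals, segs


def angular_deviation(
    traj: Trajectory,
    goals: np.ndarray | None = None,
    per_step: bool = False,
):
    """Mean absolute angular difference (degrees, [0, 180]) between the ideal
    direction from each fix to its goal and the realized direction to the
    next fix.  Zero-length steps are skipped; a fix coinciding with its goal
    is skipped with a warning (its ideal direction is undefined)."""
    xy = traj.xy
    if len(xy) < 2:
        raise ValidationError("angular_deviation needs at least 2 fixes")
    if goals is None:
        goals, _ = assign_goals(traj)
    goals = np.asarray(goals, dtype=float)
    if goals.shape[0] not in (len(xy), len(xy) - 1):
        raise ValidationError("one goal per non-final fix required")
    goals = goals[: len(xy) - 1]
    step = np.diff(xy, axis=0)
    to_goal = goals - xy[:-1]
    step_len = np.hypot(step[:, 0], step[:, 1])
    goal_len = np.hypot(to_goal[:, 0], to_goal[:, 1])
    at_goal = goal_len == 0
    if at_goal.any():
        warnings.warn(
            f"{int(at_goal.sum())} fix(es) coincide with their goal; skipped",
            stacklevel=2,
        )
    keep = (step_len > 0) & ~at_goal
    if not keep.any():
        raise ValidationError("no usable steps for angular deviation")
    ideal = np.degrees(np.arctan2(to_goal[keep, 1], to_goal[keep, 0]))
    actual = np.degrees(np.arctan2(step[keep, 1], step[keep, 0]))
    dev = np.abs(wrap_signed(actual - ideal))
    return dev if per_step else float(dev.mean())


def goal_relative_angles(traj: Trajectory, goals: np.ndarray | None = None) -> np.ndarray:
    """Signed step deviations from the ideal direction, in [-180, 180):
    each step's heading rotated so that its ideal (fix -> goal) direction is
    zero.  Used to pool directionality across trajectories of a phase."""
    if goals is None:
        goals, _ = assign_goals(traj)
    xy = traj.xy
    goals = np.asarray(goals, dtype=float)[: len(xy) - 1]
    step = np.diff(xy, axis=0)
    to_goal = goals - xy[:-1]
    keep = (np.hypot(step[:, 0], step[:, 1]) > 0) & (np.hypot(to_goal[:, 0], to_goal[:, 1]) > 0)
    ideal = np.degrees(np.arctan2(to_goal[keep, 1], to_goal[keep, 0]))
    actual = np.degrees(np.arctan2(step[keep, 1], step[keep, 0]))
    return wrap_signed(actual - ideal)


def _point_line_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray, clamp: bool) -> np.ndarray:
    d = b - a
    L2 = float(d @ d)
    if L2 == 0:
        raise ValidationError("degenerate chord (identical waypoints)")
    t = ((points - a) @ d) / L2
    if clamp:
        t = np.clip(t, 0.0, 1.0)
    proj = a + t[:, None] * d
    return np.hypot(*(points - proj).T)


def perpendicular_deviation(
    traj: Trajectory,
    segments: np.ndarray | None = None,
    clamp: bool = False,
    per_fix: bool = False,
):
    """Mean perpendicular distance (m) of each fix from its current ideal
    chord segment.  By default the distance is measured to the infinite line
    through the segment ("distance from the straight path"); ``clamp=True``
    measures to the clamped segment instead."""
    xy = traj.xy
    if segments is None:
        _, segments = assign_goals(traj)
    segments = np.asarray(segments, dtype=float)
    dev = np.empty(len(xy))
    for i in range(len(xy)):
        dev[i] = _point_line_distance(
            xy[i : i + 1], segments[i, 0], segments[i, 1], clamp
        )[0]
    return dev if per_fix else float(dev.mean())


def rayleigh_test(angles_deg) -> RayleighResult:
    """Rayleigh test of circular uniformity.

    rbar is the mean resultant length of the unit vectors, Z = n * rbar^2,
    and p uses the standard series approximation
    ``exp(-Z) * [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]``
    clamped to [0, 1].
    """
    a = np.radians(np.asarray(angles_deg, dtype=float).ravel())
    n = a.size
    if n < 4:
        raise ValidationError("too few angles (need n >= 4)")
    c = np.cos(a).mean()
    s = np.sin(a).mean()
    rbar = float(np.hypot(c, s))
    z = n * rbar**2
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    p = float(min(max(p, 0.0), 1.0))
    return RayleighResult(n=n, rbar=rbar, z=float(z), p=p)


def precision_summary(
    traj: Trajectory,
    min_locations: int = MIN_LOCATIONS,
    with_rayleigh: bool = True,
) -> PrecisionSummary | None:
    """All three precision statistics for one trajectory, or ``None`` if it
    has fewer than ``min_locations`` fixes (tracks with three or fewer
    locations are excluded from directionality analysis)."""
    if traj.n_locations < min_locations:
        return None
    goals, segs = assign_goals(traj)
    rr = None
    if with_rayleigh:
        rel = goal_relative_angles(traj, goals)
        if rel.size >= 4:
            rr = rayleigh_test(rel)
    return PrecisionSummary(
        frog_id=traj.frog_id,
        phase=traj.phase,
        n_locations=traj.n_locations,
        sc=straightness_coefficient(traj),
        mean_ang_dev_deg=angular_deviation(traj, goals),
        mean_perp_dev_m=perpendicular_deviation(traj, segs),
        rayleigh=rr,
    )
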