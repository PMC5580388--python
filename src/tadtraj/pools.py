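"""Deposition-site (pool) visits and tadpole depositions.

A pool visit is the frog actually entering a potential deposition site —
either a water-filled pool or the location of a removed / dried-out pool.
With telemetry data the observational definition is proxied by a positional
rule: a maximal run of consecutive fixes within ``r_visit`` meters of a pool
center forms one visit (nearest pool wins when radii overlap).  Deposition is
inferred from the drop in the carried tadpole count across the visit, and
only ever at an available pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SchemaError, Trajectory, ValidationError

__all__ = [
    "PoolSite",
    "VisitEvent",
    "read_pools",
    "write_pools",
    "detect_visits",
    "infer_depositions",
    "visits_per_transport",
    "explored_after_deposition",
]

STATUSES = ("available", "removed", "dry")
DEFAULT_R_VISIT = 1.0  # m; positional proxy for "actually entering" a pool


@dataclass
class PoolSite:
    """A potential tadpole deposition site with time-varying availability."""

    pool_id: str
    x: float
    y: float
    kind: str = "artificial"  # or "natural"
    # list of (status, t_from, t_to); None bounds are open
    windows: list = field(default_factory=list)

    def status_at(self, t) -> str:
        t = pd.Timestamp(t)
        for status, t_from, t_to in self.windows:
            if (t_from is None or t >= t_from) and (t_to is None or t <= t_to):
                return status
        raise ValidationError(
            f"pool {self.pool_id}: availability undefined at {t}"
        )

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class VisitEvent:
    frog_id: str
    pool_id: str
    t_arrive: pd.Timestamp
    t_depart: pd.Timestamp
    status_at_visit: str
    x: float
    y: float
    deposition: bool | None = None  # None = unknown (counts unobserved)
    tadpoles_before: float | None = None
    tadpoles_after: float | None = None

    def __post_init__(self) -> None:
        if self.deposition and self.status_at_visit != "available":
            raise ValidationError("deposition at an unavailable pool")


def read_pools(path, delimiter: str = ",") -> list[PoolSite]:
    """Read a pool CSV: pool_id, x_m, y_m, kind, status, t_from, t_to —
    one row per availability window (blank bounds = open)."""
    raw = pd.read_csv(path, delimiter=delimiter)
    for col in ("pool_id", "x_m", "y_m", "status"):
        if col not in raw.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    pools: dict[str, PoolSite] = {}
    for _, row in raw.iterrows():
        pid = str(row["pool_id"])
        if pid not in pools:
            pools[pid] = PoolSite(
                pool_id=pid,
                x=float(row["x_m"]),
                y=float(row["y_m"]),
                kind=str(row.get("kind", "artificial")),
            )
        status = str(row["status"]).strip().lower()
        if status not in STATUSES:
            raise ValidationError(f"unknown pool status {status!r}")
        t_from = pd.Timestamp(row["t_from"]) if "t_from" in raw.columns and pd.notna(row["t_from"]) else None
        t_to = pd.Timestamp(row["t_to"]) if "t_to" in raw.columns and pd.notna(row["t_to"]) else None
        pools[pid].windows.append((status, t_from, t_to))
    return list(pools.values())


def write_pools(pools: list[PoolSite], path, delimiter: str = ",") -> None:
    rows = []
    for p in pools:
        for status, t_from, t_to in p.windows:
            rows.append(
                {
                    "pool_id": p.pool_id,
                    "x_m": p.x,
                    "y_m": p.y,
                    "kind": p.kind,
                    "status": status,
                    "t_from": "" if t_from is None else t_from.isoformat(),
                    "t_to": "" if t_to is None else t_to.isoformat(),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, sep=delimiter)


def detect_visits(
    fixes: pd.DataFrame,
    pools: list[PoolSite],
    r_visit: float = DEFAULT_R_VISIT,
    merge_gap: pd.Timedelta = pd.Timedelta(minutes=30),
) -> list[VisitEvent]:
    """Detect pool visits along one frog's fix sequence.

    Maximal runs of consecutive fixes within ``r_visit`` of a pool center
    become one :class:`VisitEvent` (the nearest pool wins when radii
    overlap).  A visit interrupted by a single out-of-radius fix shorter than
    ``merge_gap`` is merged back into one event (tracking noise).
    """
    if not pools:
        raise ValidationError("pool list is empty")
    if r_visit <= 0:
        raise ValidationError("r_visit must be positive")
    centers = np.array([[p.x, p.y] for p in pools])
    if len(pools) > 1:
        d = np.hypot(
            centers[:, None, 0] - centers[None, :, 0],
            centers[:, None, 1] - centers[None, :, 1],
        )
        np.fill_diagonal(d, np.inf)
        if d.min() < 2 * r_visit:
            warnings.warn(
                "pools closer than 2*r_visit: visit attribution may be ambiguous",
                stacklevel=2,
            )
    fixes = fixes.reset_index(drop=True)
    xy = fixes[["x_m", "y_m"]].to_numpy(dtype=float)
    dists = np.hypot(xy[:, 0, None] - centers[None, :, 0], xy[:, 1, None] - centers[None, :, 1])
    nearest = dists.argmin(axis=1)
    inside = dists[np.arange(len(xy)), nearest] <= r_visit
    pool_at_fix = np.where(inside, nearest, -1)

    # merge single-fix gaps shorter than merge_gap
    ts = fixes["timestamp"]
    for i in range(1, len(xy) - 1):
        if (
            pool_at_fix[i] == -1
            and pool_at_fix[i - 1] != -1
            and pool_at_fix[i + 1] == pool_at_fix[i - 1]
            and (ts[i + 1] - ts[i - 1]) <= merge_gap
        ):
            pool_at_fix[i] = pool_at_fix[i - 1]

    events: list[VisitEvent] = []
    frog_id = str(fixes["frog_id"].iloc[0])
    i = 0
    while i < len(xy):
        pid = pool_at_fix[i]
        if pid == -1:
            i += 1
            continue
        j = i
        while j + 1 < len(xy) and pool_at_fix[j + 1] == pid:
            j += 1
        pool = pools[pid]
        events.append(
            VisitEvent(
                frog_id=frog_id,
                pool_id=pool.pool_id,
                t_arrive=ts[i],
                t_depart=ts[j],
                status_at_visit=pool.status_at(ts[i]),
                x=pool.x,
                y=pool.y,
            )
        )
        i = j + 1
    events.sort(key=lambda v: v.t_arrive)
    return events


def infer_depositions(visits: list[VisitEvent], fixes: pd.DataFrame) -> list[VisitEvent]:
    """Fill the deposition flag of each visit from the carried tadpole counts.

    ``tadpoles_before`` is the last known count at or before arrival and
    ``tadpoles_after`` the first known count after departure.  Deposition is
    true iff the pool was available and the count strictly dropped; with
    unknown counts the flag stays ``None`` (never guessed).  A count increase
    across a visit is a validation error (tadpoles cannot be gained).
    """
    fixes = fixes.reset_index(drop=True)
    ts = fixes["timestamp"]
    counts = fixes["tadpoles"]
    for v in visits:
        before = counts[ts <= v.t_arrive].dropna()
        after = counts[ts > v.t_depart].dropna()
        v.tadpoles_before = float(before.iloc[-1]) if len(before) else None
        v.tadpoles_after = float(after.iloc[0]) if len(after) else None
        if v.tadpoles_before is None or v.tadpoles_after is None:
            v.deposition = None
            continue
        if v.tadpoles_after > v.tadpoles_before:
            raise ValidationError(
                f"tadpole count increased across visit to {v.pool_id} "
                f"({v.tadpoles_before} -> {v.tadpoles_after})"
            )
        dropped = v.tadpoles_after < v.tadpoles_before
        v.deposition = bool(dropped and v.status_at_visit == "available")
    return visits


def visits_per_transport(visits_by_tt: list[list[VisitEvent]]) -> dict:
    """Mean, range and available/non-available breakdown of distinct
    deposition sites visited per transport event.

    Each element of ``visits_by_tt`` is the visit list of one tracked
    transport; transports with only one final deposition site and no detailed
    track should already be excluded upstream."""
    if not visits_by_tt:
        raise ValidationError("no transports supplied")
    counts, n_avail, n_unavail = [], 0, 0
    for visits in visits_by_tt:
        seen: dict[str, str] = {}
        for v in visits:
            seen.setdefault(v.pool_id, v.status_at_visit)
        counts.append(len(seen))
        n_avail += sum(1 for s in seen.values() if s == "available")
        n_unavail += sum(1 for s in seen.values() if s != "available")
    counts_arr = np.array(counts)
    return {
        "mean": float(counts_arr.mean()),
        "min": int(counts_arr.min()),
        "max": int(counts_arr.max()),
        "n_transports": len(counts),
        "n_available_visits": n_avail,
        "n_unavailable_visits": n_unavail,
    }


def explored_after_deposition(visits: list[VisitEvent]) -> bool:
    """True if the frog visited any further pool after depositing all its
    tadpoles (a visit arriving with a known count of zero)."""
    return any(v.tadpoles_before == 0 for v in visits)
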