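"""Synthetic study generator.

Emulates the field design the analysis pipeline assumes: a cross-shaped
array of 13 artificial pools at 20 m spacing with every second pool removed
(8 available), male territories scattered around the array, and
stop-and-go, goal-directed tadpole-transport movement sampled every 30-60
minutes within the 07:00-19:00 daylight window, with nights skipped.

Movement model: a two-state (move / pause) Markov walk at the fix cadence.
In the move state the heading is von Mises-distributed around the bearing to
the current goal with concentration ``kappa`` and the step length is
exponential with a mean proportional to the fix interval, multiplied by
``speed_ratio_tt`` while tadpoles are carried (frogs move faster when
transporting) and by a lognormal per-frog factor (individual variation that
the random-intercept models are meant to absorb).  Per-step speed is capped
at 70 m/h, the maximum ever recorded between consecutive fixes.

Every simulated frog carries a full :class:`GroundTruth` record (itinerary,
per-pool deposits, per-fix movement state and phase label, true pre-encounter
path length, true parameters) so that segmentation, visit detection and the
statistical models can be validated against known truth.

Geometric conventions that make truth recoverable from fixes: visit fixes sit
at the pool center (plus observation jitter), travel fixes are rejected
within ``pool_exclusion_m`` of any non-goal pool, and homing fixes stay at
least ``home_arrival_m`` from the territory center until arrival.  Field
visits were classified by direct observation; the generator encodes the same
unambiguity positionally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import Territory, ValidationError
from .pools import PoolSite

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulationError",
    "build_landscape",
    "simulate_transport",
    "simulate_study",
    "simulate_covariates",
    "simulate_speed_dataset",
    "simulate_selection_dataset",
]

START_DATE = pd.Timestamp("2015-02-01")


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults mirror the field design: 13 pools in a cross at 20 m spacing
    with every second one removed, mean tadpole load 8.5 (sd 4.9, clipped to
    1-25), fixes every 30-60 min during 07:00-19:00, a 1.41 speed factor
    while carrying tadpoles, and 7 m home-territory radius.
    """

    seed: int = 0
    n_frogs: int = 16
    kappa: float = 8.0  # von Mises heading concentration toward the goal
    p_move: float = 0.75  # P(pause -> move) per fix interval, transport
    p_pause: float = 0.2  # P(move -> pause) per fix interval, transport
    p_move_ht: float = 0.2  # homing is dominated by longer rest bouts
    p_pause_ht: float = 0.8
    step_rate_move: float = 0.38  # mean m per minute while moving (homing)
    speed_ratio_tt: float = 1.41  # speed factor while carrying tadpoles
    frog_speed_sd: float = 0.15  # lognormal sd of the per-frog speed factor
    fix_interval_min: tuple[float, float] = (30.0, 60.0)
    pool_spacing: float = 20.0
    n_pools: int = 13
    removed_every_second: bool = True
    tadpole_mean: float = 8.5
    tadpole_sd: float = 4.9
    tadpole_range: tuple[int, int] = (1, 25)
    day_start_hour: float = 7.0
    day_end_hour: float = 19.0
    r_territory: float = 7.0
    territory_annulus: tuple[float, float] = (10.0, 60.0)
    jitter_sd: float = 0.5  # positional observation noise (m)
    pool_exclusion_m: float = 4.5  # travel fixes keep this far from non-goal pools
    home_clearance_m: float = 9.5  # homing step ending inside this ring = return home
    speed_cap_m_per_h: float = 70.0  # per-step cap while transporting
    speed_cap_ht_m_per_h: float = 20.0  # homing steps are never sprints
    home_radius_m: float = 4.5  # the returned frog settles at the territory edge
    step_shape: float = 2.0  # gamma shape of the step-length distribution
    max_days: int = 5
    p_nearest: float = 0.7  # itinerary: pick the nearest candidate pool
    visit_probs: tuple[float, ...] = (0.2, 0.35, 0.3, 0.15)  # P(1..4 pools)

    def __post_init__(self) -> None:
        for p in (self.p_move, self.p_pause, self.p_move_ht, self.p_pause_ht):
            if not 0 <= p <= 1:
                raise ValidationError("transition probabilities must be in [0, 1]")
        if self.kappa < 0 or self.step_rate_move < 0:
            raise ValidationError("rates must be nonnegative")
        if abs(sum(self.visit_probs) - 1.0) > 1e-9:
            raise ValidationError("visit_probs must sum to 1")


@dataclass
class GroundTruth:
    frog_id: str
    itinerary: list[str]  # ordered pool ids visited
    deposits: dict[str, int]  # pool id -> tadpoles deposited
    initial_load: int
    states: list[str]  # per observed fix: start/move/pause/at_pool
    phases: list[str]  # per observed fix: TT/HT (split fix labelled TT+HT)
    pre_encounter_path_m: float
    kappa: float
    speed_ratio_tt: float
    complete: bool = True


def _rng_for(cfg: SimConfig, stream: int) -> np.random.Generator:
    """Named substream: every stochastic operation draws from its own child
    of the config seed, so adding operations never perturbs existing ones."""
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


_STREAM_LANDSCAPE = 0
_STREAM_COVARIATES = 1
_STREAM_FROG0 = 100


def build_landscape(cfg: SimConfig) -> tuple[list[PoolSite], list[Territory]]:
    """Cross-shaped pool array plus territory centers.

    13 pools: one at the origin and three per arm at ``pool_spacing``.  With
    ``removed_every_second`` the alternating pattern from the center removes
    the origin and the 40 m ring (5 pools), leaving 8 available.  Territory
    centers are drawn uniformly in an annulus around the array center,
    rejecting draws closer than 12 m to any pool so that pool visits and
    homing arrivals stay unambiguous.
    """
    spacing = cfg.pool_spacing
    offsets = [(0, 0)]
    for k in (1, 2, 3):
        offsets += [(k * spacing, 0), (-k * spacing, 0), (0, k * spacing), (0, -k * spacing)]
    offsets = offsets[: cfg.n_pools]
    pools = []
    for i, (x, y) in enumerate(offsets):
        ring = int(round((abs(x) + abs(y)) / spacing))
        removed = cfg.removed_every_second and ring % 2 == 0
        status = "removed" if removed else "available"
        pools.append(
            PoolSite(
                pool_id=f"P{i:02d}", x=float(x), y=float(y),
                kind="artificial", windows=[(status, None, None)],
            )
        )
    rng = _rng_for(cfg, _STREAM_LANDSCAPE)
    centers = np.array([[p.x, p.y] for p in pools])
    territories = []
    r_lo, r_hi = cfg.territory_annulus
    for i in range(cfg.n_frogs):
        while True:
            r = math.sqrt(rng.uniform(r_lo**2, r_hi**2))
            th = rng.uniform(0, 2 * math.pi)
            c = np.array([r * math.cos(th), r * math.sin(th)])
            if np.hypot(*(centers - c).T).min() >= 12.0:
                break
        territories.append(Territory(frog_id=f"F{i:02d}", center=c, n_captures=1))
    return pools, territories


def _draw_load(cfg: SimConfig, rng: np.random.Generator) -> int:
    lo, hi = cfg.tadpole_range
    while True:
        v = int(round(rng.normal(cfg.tadpole_mean, cfg.tadpole_sd)))
        if lo <= v <= hi:
            return v


def _draw_itinerary(cfg, pools, start_xy, rng) -> list[PoolSite]:
    """1-4 pools; nearest-unvisited-first with probability ``p_nearest``,
    otherwise a random known pool; the final pool must be available (the
    transport ends with a deposition)."""
    n_visit = int(rng.choice(np.arange(1, len(cfg.visit_probs) + 1), p=cfg.visit_probs))
    chosen: list[PoolSite] = []
    pos = np.asarray(start_xy, dtype=float)
    remaining = list(pools)
    for step in range(n_visit):
        last = step == n_visit - 1
        cands = [p for p in remaining if (not last) or p.status_at(START_DATE) == "available"]
        if not cands:
            break
        d = np.array([np.hypot(*(p.xy - pos)) for p in cands])
        if rng.random() < cfg.p_nearest:
            pick = cands[int(d.argmin())]
        else:
            pick = cands[int(rng.integers(len(cands)))]
        chosen.append(pick)
        remaining.remove(pick)
        pos = pick.xy
    if not chosen or chosen[-1].status_at(START_DATE) != "available":
        avail = [p for p in pools if p.status_at(START_DATE) == "available" and p not in chosen]
        d = np.array([np.hypot(*(p.xy - pos)) for p in avail])
        chosen.append(avail[int(d.argmin())])
    return chosen


def _split_deposits(load: int, available_ids: list[str], rng) -> dict[str, int]:
    # every receiving pool gets >=1 tadpole; with a small load only the last
    # pools of the itinerary receive (the transport ends with a deposition)
    ids = available_ids[-min(load, len(available_ids)):]
    m = len(ids)
    if m == 1:
        return {ids[0]: load}
    extra = rng.multinomial(load - m, np.full(m, 1.0 / m))
    return {pid: int(1 + e) for pid, e in zip(ids, extra)}


def _advance_clock(t: pd.Timestamp, dt_min: float, cfg: SimConfig) -> tuple[pd.Timestamp, bool]:
    """Advance the sampling clock, skipping the night when the next fix would
    fall after the end of the tracking day."""
    t_next = (t + pd.Timedelta(minutes=float(dt_min))).floor("min")
    day_end = t.normalize() + pd.Timedelta(hours=cfg.day_end_hour)
    if t_next <= day_end:
        return t_next, False
    morning = t.normalize() + pd.Timedelta(days=1, hours=cfg.day_start_hour)
    return (morning + pd.Timedelta(minutes=float(dt_min) / 2.0)).floor("min"), True


def simulate_transport(
    cfg: SimConfig,
    pools: list[PoolSite],
    territory: Territory,
    frog_id: str,
    rng: np.random.Generator,
    require_completion: bool = True,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one tadpole transport + homing track for one frog.

    Returns the observed fix DataFrame (jittered positions, encounter-trimmed
    start) and the ground truth.  Raises :class:`SimulationError` if the frog
    does not complete transport and homing within ``max_days`` (or truncates
    and flags the truth incomplete when ``require_completion`` is false).
    """
    load = _draw_load(cfg, rng)
    itinerary = _draw_itinerary(cfg, pools, territory.center, rng)
    avail_ids = [p.pool_id for p in itinerary if p.status_at(START_DATE) == "available"]
    deposits = _split_deposits(load, avail_ids, rng)
    frog_mult = float(np.exp(rng.normal(0.0, cfg.frog_speed_sd)))
    centers = np.array([[p.x, p.y] for p in pools])

    t = START_DATE + pd.Timedelta(hours=cfg.day_start_hour + rng.uniform(0.5, 4.0))
    t = t.floor("min")
    pos = territory.center.copy()
    tadpoles = load
    state = "move"
    goal_idx = 0
    phase = "TT"
    dwell_left = 0

    rows = [(t, pos[0], pos[1], tadpoles, "start", phase, None)]
    deadline = t + pd.Timedelta(days=cfg.max_days)
    complete = True

    def goal_point():
        if phase == "HT":
            return territory.center
        return itinerary[goal_idx].xy

    def blocked(cand: np.ndarray) -> bool:
        goal = goal_point()
        d = np.hypot(*(centers - cand).T)
        for j in range(len(pools)):
            if d[j] < cfg.pool_exclusion_m and not np.allclose(centers[j], goal):
                return True
        if phase == "HT":
            return False  # arrival handled by caller
        return bool(np.hypot(*(cand - territory.center)) < 0.0)

    while True:
        dt_min = float(rng.uniform(*cfg.fix_interval_min))
        t, _night = _advance_clock(t, dt_min, cfg)
        if t > deadline:
            if require_completion:
                raise SimulationError(
                    f"{frog_id}: goal unreachable within {cfg.max_days} days"
                )
            complete = False
            break

        if dwell_left > 0:
            dwell_left -= 1
            rows.append((t, pos[0], pos[1], tadpoles, "at_pool", phase, itinerary[goal_idx].pool_id))
            if dwell_left == 0:
                if phase == "TT" and goal_idx == len(itinerary) - 1:
                    phase = "HT"
                    state = "pause"  # post-deposition rest before homing
                elif phase == "TT":
                    goal_idx += 1
            continue

        pm = cfg.p_move if phase == "TT" else cfg.p_move_ht
        pp = cfg.p_pause if phase == "TT" else cfg.p_pause_ht
        if state == "pause":
            if rng.random() < pm:
                state = "move"
        else:
            if rng.random() < pp:
                state = "pause"

        if state == "pause":
            rows.append((t, pos[0], pos[1], tadpoles, "pause", phase, None))
            continue

        goal = goal_point()
        mult = frog_mult * (cfg.speed_ratio_tt if tadpoles > 0 else 1.0)
        mean_len = cfg.step_rate_move * dt_min * mult
        cap_mh = cfg.speed_cap_m_per_h if phase == "TT" else cfg.speed_cap_ht_m_per_h
        cap = cap_mh * dt_min / 60.0
        arrived = False
        cand = pos
        for _attempt in range(40):
            theta = math.atan2(goal[1] - pos[1], goal[0] - pos[0])
            if cfg.kappa > 0:
                heading = rng.vonmises(theta, cfg.kappa)
            else:
                heading = rng.uniform(-math.pi, math.pi)
            L = min(rng.gamma(cfg.step_shape, mean_len / cfg.step_shape), cap)
            cand = pos + L * np.array([math.cos(heading), math.sin(heading)])
            if phase == "HT":
                # arrival is endpoint-triggered: a step ending inside the
                # clearance ring finishes the approach to the center within
                # the same interval (bounded extension, never a far teleport);
                # travel fixes therefore stay outside the ring, keeping the
                # radius rule that detects the return unambiguous under
                # observation noise
                d_home = float(np.hypot(*(cand - territory.center)))
                if d_home <= cfg.home_clearance_m:
                    arrived = True
                    break
                if not blocked(cand):
                    break
            else:
                if _segment_near(pos, cand, goal, cfg.pool_exclusion_m):
                    arrived = True
                    break
                if not blocked(cand):
                    break
        else:
            rows.append((t, pos[0], pos[1], tadpoles, "pause", phase, None))
            continue

        if arrived and phase == "HT":
            # settle just inside the territory: pull an endpoint that landed in
            # the clearance ring to home_radius_m from the center (bounded
            # extension of at most home_clearance_m - home_radius_m)
            d_home = float(np.hypot(*(cand - territory.center)))
            if d_home > cfg.home_radius_m:
                u = (cand - territory.center) / d_home
                cand = territory.center + cfg.home_radius_m * u
            pos = cand
            rows.append((t, pos[0], pos[1], tadpoles, "move", "HT", None))
            break
        if arrived:
            pool = itinerary[goal_idx]
            pos = pool.xy.copy()
            rows.append((t, pos[0], pos[1], tadpoles, "at_pool", phase, pool.pool_id))
            if pool.pool_id in deposits:
                tadpoles -= deposits[pool.pool_id]
                dwell_left = int(rng.integers(1, 4))  # depositing takes time
            else:
                dwell_left = int(rng.integers(0, 3))
            if dwell_left == 0:
                if goal_idx == len(itinerary) - 1:
                    phase = "HT"
                    state = "pause"
                else:
                    goal_idx += 1
            continue
        pos = cand
        rows.append((t, pos[0], pos[1], tadpoles, "move", phase, None))

    df = pd.DataFrame(
        rows, columns=["timestamp", "x_m", "y_m", "tadpoles", "state", "phase", "at_pool"]
    )

    # phase labels per fix: TT through the last fix of the visit at the last
    # deposition pool.  Post-deposition rest keeps the frog at the pool, so
    # the visit (and with it the TT) ends only when the frog actually leaves;
    # the split fix belongs to both phases.
    last_pool = itinerary[-1]
    at_last = np.flatnonzero(df["at_pool"].to_numpy() == last_pool.pool_id)
    phases = ["TT"] * len(df)
    if at_last.size:
        split = int(at_last[-1])
        xs, ys = df["x_m"].to_numpy(), df["y_m"].to_numpy()
        while split + 1 < len(df) and xs[split + 1] == last_pool.x and ys[split + 1] == last_pool.y:
            split += 1
        for i in range(split + 1, len(df)):
            phases[i] = "HT"
    df["phase"] = phases

    # encounter trimming: the observed track starts 1-3 fixes into the walk
    # (frogs were found already transporting), leaving at least three fixes
    # before the first pool arrival.
    at_pool_idx = np.flatnonzero(df["at_pool"].notna().to_numpy())
    first_arrival = int(at_pool_idx[0]) if at_pool_idx.size else len(df)
    max_k = min(3, max(first_arrival - 3, 0))
    k = int(rng.integers(1, max_k + 1)) if max_k >= 1 else 0
    true_xy = df[["x_m", "y_m"]].to_numpy()
    pre_path = float(np.hypot(*np.diff(true_xy[: k + 1], axis=0).T).sum()) if k else 0.0

    obs = df.iloc[k:].reset_index(drop=True).copy()
    # observation noise is tied to the true position: a pausing frog is
    # re-recorded at identical coordinates (field step speeds include exact
    # zeros), so the jitter is redrawn only when the frog actually moved
    jitter = rng.normal(0.0, cfg.jitter_sd, size=(len(obs), 2))
    xy_true = obs[["x_m", "y_m"]].to_numpy()
    for i in range(1, len(obs)):
        if np.array_equal(xy_true[i], xy_true[i - 1]):
            jitter[i] = jitter[i - 1]
    obs["x_m"] = xy_true[:, 0] + jitter[:, 0]
    obs["y_m"] = xy_true[:, 1] + jitter[:, 1]
    obs["frog_id"] = frog_id
    obs["behavior"] = np.where(obs["tadpoles"].to_numpy() > 0, "transport", "other")

    truth = GroundTruth(
        frog_id=frog_id,
        itinerary=[p.pool_id for p in itinerary],
        deposits=deposits,
        initial_load=load,
        states=obs["state"].tolist(),
        phases=obs["phase"].tolist(),
        pre_encounter_path_m=pre_path,
        kappa=cfg.kappa,
        speed_ratio_tt=cfg.speed_ratio_tt,
        complete=complete,
    )
    fixes = obs[["frog_id", "timestamp", "x_m", "y_m", "tadpoles", "behavior"]].copy()
    return fixes, truth


def _segment_near(a: np.ndarray, b: np.ndarray, point: np.ndarray, radius: float) -> bool:
    """Does the segment a->b pass within ``radius`` of ``point``?"""
    d = b - a
    L2 = float(d @ d)
    if L2 == 0:
        return bool(np.hypot(*(point - a)) <= radius)
    tt = float(np.clip((point - a) @ d / L2, 0.0, 1.0))
    proj = a + tt * d
    return bool(np.hypot(*(point - proj)) <= radius)


def simulate_study(
    cfg: SimConfig, require_completion: bool = False
) -> tuple[list[PoolSite], dict[str, Territory], dict[str, pd.DataFrame], dict[str, GroundTruth]]:
    """Simulate the full study: landscape plus one transport track per frog.

    By default frogs that do not finish transport and homing within
    ``max_days`` are kept as truncated tracks flagged incomplete in the
    truth (the field study likewise had individuals that never finished);
    ``require_completion=True`` raises instead."""
    pools, territories = build_landscape(cfg)
    fixes: dict[str, pd.DataFrame] = {}
    truths: dict[str, GroundTruth] = {}
    terr_map: dict[str, Territory] = {}
    for i, terr in enumerate(territories):
        rng = _rng_for(cfg, _STREAM_FROG0 + i)
        fid = terr.frog_id
        fixes[fid], truths[fid] = simulate_transport(
            cfg, pools, terr, fid, rng, require_completion=require_completion
        )
        terr_map[fid] = terr
    return pools, terr_map, fixes, truths


# ---------------------------------------------------------------------------
# Covariates and model-recovery datasets


def simulate_covariates(
    cfg: SimConfig,
    n_days: int = 30,
    temp_mean: float = 26.0,
    temp_amplitude: float = 3.0,
    temp_noise_sd: float = 1.0,
    rain_prob: float = 0.3,
    rain_shape: float = 1.5,
    rain_scale_mm: float = 4.0,
) -> pd.DataFrame:
    """Weather series on the four 3-h daylight intervals (07-10, 10-13,
    13-16, 16-19): sinusoidal daily temperature cycle plus noise, and
    zero-inflated-gamma interval rainfall."""
    rng = _rng_for(cfg, _STREAM_COVARIATES)
    rows = []
    for day in range(n_days):
        for start in (7, 10, 13, 16):
            mid = start + 1.5
            temp = temp_mean + temp_amplitude * math.sin(2 * math.pi * (mid - 9.0) / 24.0)
            if temp_noise_sd > 0:
                temp += rng.normal(0.0, temp_noise_sd)
            rain = 0.0
            if rain_prob > 0 and rng.random() < rain_prob:
                rain = float(rng.gamma(rain_shape, rain_scale_mm))
            rows.append(
                {
                    "date": (START_DATE + pd.Timedelta(days=day)).date().isoformat(),
                    "interval_start_h": start,
                    "temperature_c": float(temp),
                    "rain_mm": rain,
                }
            )
    return pd.DataFrame(rows)


def simulate_speed_dataset(
    rng: np.random.Generator,
    n_frogs: int = 16,
    mean_tt: float = 10.16,
    mean_ht: float = 7.22,
    shape: float = 5.0,
    frog_sd: float = 0.2,
) -> pd.DataFrame:
    """Per-trajectory average speeds for the tadpole-effect model: one TT and
    one HT speed per frog, gamma-distributed (given the frog) around phase
    means with a lognormal per-frog random effect on the log scale."""
    rows = []
    for i in range(n_frogs):
        b = rng.normal(0.0, frog_sd)
        for phase, mu in (("TT", mean_tt), ("HT", mean_ht)):
            m = math.exp(math.log(mu) + b)
            rows.append(
                {
                    "frog_id": f"F{i:02d}",
                    "phase": phase,
                    "tadpoles_present": 1.0 if phase == "TT" else 0.0,
                    "speed_m_per_h": float(rng.gamma(shape, m / shape)),
                }
            )
    return pd.DataFrame(rows)


def simulate_selection_dataset(
    rng: np.random.Generator,
    n: int = 200,
    n_groups: int = 20,
    effects: dict[str, float] | None = None,
    candidates: tuple[str, ...] = ("temperature", "rain", "afternoon", "tadpoles_present"),
    sigma: float = 1.0,
    group_sd: float = 0.5,
) -> pd.DataFrame:
    """Observation table for all-subset selection recovery experiments:
    ``n`` rows, standardized candidate covariates, Gaussian response with
    the configured true effects (units of the residual sd) and a group
    random intercept."""
    effects = effects or {}
    data = {c: rng.normal(0.0, 1.0, size=n) for c in candidates}
    groups = rng.integers(0, n_groups, size=n)
    b = rng.normal(0.0, group_sd, size=n_groups)
    y = b[groups] + rng.normal(0.0, sigma, size=n)
    for c, eff in effects.items():
        y = y + eff * sigma * data[c]
    data["speed"] = y
    data["frog_id"] = [f"G{g:02d}" for g in groups]
    return pd.DataFrame(data)
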