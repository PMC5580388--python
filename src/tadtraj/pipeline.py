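"""End-to-end analysis and simulation runners.

``run_simulate`` writes a synthetic study (fix/pool/territory CSVs in the
dialects the readers accept, plus a ground-truth JSON and a manifest).
``run_analyze`` runs the full analysis on any such inputs: visit detection,
deposition inference, phase segmentation, the per-trajectory summary tables
(transport and homing), the precision statistics with pooled Rayleigh tests,
and the mixed-model comparisons.  Identical inputs and configuration yield
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    DaylightWindow,
    Territory,
    Trajectory,
    ValidationError,
    active_duration,
    mean_speed,
    path_length,
    read_fixes,
    read_territories,
    segment_phases,
    territory_centers,
    write_fixes,
)
from .models import ModelSpec, compare_to_null, fit_mixed_model
from .pools import (
    VisitEvent,
    detect_visits,
    explored_after_deposition,
    infer_depositions,
    read_pools,
    visits_per_transport,
    write_pools,
)
from .precision import goal_relative_angles, precision_summary, rayleigh_test
from .simulate import SimConfig, simulate_study

__all__ = ["RunConfig", "AnalysisResult", "run_analyze", "run_simulate"]


@dataclass
class RunConfig:
    fixes_path: str
    pools_path: str
    territories_path: str | None = None
    truth_path: str | None = None
    out_dir: str = "tadtraj_out"
    column_map: dict = field(default_factory=dict)
    r_visit: float = 1.0
    r_home: float = 7.0
    min_locations: int = 4
    speed_family: str = "gamma"  # family for the speed model
    fit_models: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("r_visit", "r_home", "min_locations"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class AnalysisResult:
    trajectories: dict[str, tuple[Trajectory, Trajectory]]
    visits: dict[str, list[VisitEvent]]
    territories: dict[str, Territory]
    table_tt: pd.DataFrame
    table_ht: pd.DataFrame
    precision: pd.DataFrame
    visit_table: pd.DataFrame
    visit_stats: dict
    rayleigh: dict
    models: dict


def _visit_row(v: VisitEvent) -> dict:
    return {
        "frog_id": v.frog_id,
        "pool_id": v.pool_id,
        "t_arrive": v.t_arrive.isoformat(),
        "t_depart": v.t_depart.isoformat(),
        "status_at_visit": v.status_at_visit,
        "x_m": v.x,
        "y_m": v.y,
        "deposition": "" if v.deposition is None else int(v.deposition),
        "tadpoles_before": "" if v.tadpoles_before is None else v.tadpoles_before,
        "tadpoles_after": "" if v.tadpoles_after is None else v.tadpoles_after,
    }


def _tt_row(frog: str, tt: Trajectory, visits: list[VisitEvent], window: DaylightWindow) -> dict:
    """One transport-summary row: distances, duration, speed, pools visited
    (with available / non-available counts), the interpolated total distance,
    the straight-line (waypoint-chord) distance, and the straightness
    coefficient over the estimated full transport."""
    tracked = path_length(tt)
    interp = tt.interpolated_start_m or 0.0
    seen: dict[str, str] = {}
    for v in sorted(visits, key=lambda v: v.t_arrive):
        if v.t_arrive <= tt.times.iloc[-1]:
            seen.setdefault(v.pool_id, v.status_at_visit)
    n_avail = sum(1 for s in seen.values() if s == "available")
    chord = float(np.hypot(*np.diff(tt.waypoints, axis=0).T).sum())
    total = interp + tracked
    tads = tt.fixes["tadpoles"].dropna()
    return {
        "frog_id": frog,
        "n_tadpoles": float(tads.iloc[0]) if len(tads) else np.nan,
        "tracked_distance_m": tracked,
        "total_time_h": active_duration(tt, window),
        "mean_speed_m_per_h": mean_speed(tt, window),
        "n_sites_visited": len(seen),
        "n_available": n_avail,
        "n_unavailable": len(seen) - n_avail,
        "interpolated_start_m": interp,
        "total_tt_distance_m": total,
        "straight_line_distance_m": interp + chord,
        "straightness_coefficient": min((interp + chord) / total, 1.0) if total > 0 else np.nan,
    }


def _ht_row(frog: str, ht: Trajectory, window: DaylightWindow) -> dict:
    dur = active_duration(ht, window)
    return {
        "frog_id": frog,
        "tracked_distance_m": path_length(ht),
        "straight_line_distance_m": float(np.hypot(*(ht.waypoints[-1] - ht.waypoints[0]))),
        "duration_h": dur,
        "overnight": int(ht.times.iloc[-1].date() != ht.times.iloc[0].date()),
        "mean_speed_m_per_h": mean_speed(ht, window),
        "straightness_coefficient": min(
            float(np.hypot(*(ht.waypoints[-1] - ht.waypoints[0]))) / path_length(ht), 1.0
        ),
        "complete": int(ht.complete),
    }


def analyze(
    fixes_by_frog: dict[str, pd.DataFrame],
    pools,
    territories: dict[str, Territory],
    r_visit: float = 1.0,
    r_home: float = 7.0,
    min_locations: int = 4,
    fit_models: bool = True,
    window: DaylightWindow = DaylightWindow(),
) -> AnalysisResult:
    """Run the full analysis in memory; see :func:`run_analyze` for the
    file-based wrapper."""
    trajectories: dict[str, tuple[Trajectory, Trajectory]] = {}
    visits_map: dict[str, list[VisitEvent]] = {}
    tt_rows, ht_rows, prec_rows, visit_rows = [], [], [], []
    pooled_angles: dict[str, list] = {"TT": [], "HT": []}

    for frog, fixes in fixes_by_frog.items():
        if frog not in territories:
            warnings.warn(f"no territory for frog {frog}; skipped", stacklevel=2)
            continue
        visits = detect_visits(fixes, pools, r_visit=r_visit)
        visits = infer_depositions(visits, fixes)
        visits_map[frog] = visits
        visit_rows.extend(_visit_row(v) for v in visits)
        if not any(v.deposition for v in visits):
            warnings.warn(f"no deposition for frog {frog}; track not segmented", stacklevel=2)
            continue
        try:
            tt, ht = segment_phases(fixes, visits, territories[frog], r_home=r_home)
        except ValidationError as exc:
            warnings.warn(f"frog {frog}: {exc}", stacklevel=2)
            continue
        trajectories[frog] = (tt, ht)
        tt_rows.append(_tt_row(frog, tt, visits, window))
        ht_rows.append(_ht_row(frog, ht, window))
        for traj in (tt, ht):
            ps = precision_summary(traj, min_locations=min_locations)
            if ps is None:
                continue
            prec_rows.append(
                {
                    "frog_id": ps.frog_id,
                    "phase": ps.phase,
                    "n_locations": ps.n_locations,
                    "sc": ps.sc,
                    "mean_ang_dev_deg": ps.mean_ang_dev_deg,
                    "mean_perp_dev_m": ps.mean_perp_dev_m,
                    "rayleigh_rbar": np.nan if ps.rayleigh is None else ps.rayleigh.rbar,
                    "rayleigh_p": np.nan if ps.rayleigh is None else ps.rayleigh.p,
                }
            )
            pooled_angles[traj.phase].append(goal_relative_angles(traj))

    precision = pd.DataFrame(
        prec_rows,
        columns=[
            "frog_id", "phase", "n_locations", "sc",
            "mean_ang_dev_deg", "mean_perp_dev_m", "rayleigh_rbar", "rayleigh_p",
        ],
    )
    rayleigh = {}
    for phase, chunks in pooled_angles.items():
        if chunks:
            angles = np.concatenate(chunks)
            if angles.size >= 4:
                rayleigh[phase] = rayleigh_test(angles)

    visit_stats = {}
    eligible = [v for f, v in visits_map.items() if f in trajectories]
    if eligible:
        visit_stats = visits_per_transport(eligible)
        visit_stats["any_exploration_after_deposition"] = any(
            explored_after_deposition(v) for v in eligible
        )

    models: dict = {}
    if fit_models and trajectories:
        models = _fit_pipeline_models(trajectories, visits_map, precision)

    return AnalysisResult(
        trajectories=trajectories,
        visits=visits_map,
        territories=territories,
        table_tt=pd.DataFrame(tt_rows),
        table_ht=pd.DataFrame(ht_rows),
        precision=precision,
        visit_table=pd.DataFrame(visit_rows),
        visit_stats=visit_stats,
        rayleigh=rayleigh,
        models=models,
    )


def _fit_pipeline_models(trajectories, visits_map, precision) -> dict:
    """The pipeline's mixed-model comparisons: speed ~ tadpoles present, and
    precision ~ whether an unavailable pool was encountered, each judged
    against its null by Delta AICc."""
    window = DaylightWindow()
    speed_rows = []
    unavailable: dict[str, bool] = {}
    for frog, (tt, ht) in trajectories.items():
        unavailable[frog] = any(
            v.status_at_visit != "available" for v in visits_map.get(frog, [])
        )
        for traj, tp in ((tt, 1.0), (ht, 0.0)):
            speed_rows.append(
                {
                    "frog_id": frog,
                    "tadpoles_present": tp,
                    "speed_m_per_h": mean_speed(traj, window),
                }
            )
    speed_df = pd.DataFrame(speed_rows)
    out: dict = {}
    try:
        full = fit_mixed_model(
            ModelSpec("speed_m_per_h", family="gamma", fixed_terms=("tadpoles_present",)),
            speed_df,
        )
        null = fit_mixed_model(ModelSpec("speed_m_per_h", family="gamma"), speed_df)
        out["speed_vs_tadpoles"] = {
            "full": full,
            "null": null,
            **compare_to_null(full, null),
            "speed_ratio": float(np.exp(full.coefficients["tadpoles_present"][0])),
        }
    except (ValidationError, np.linalg.LinAlgError) as exc:
        warnings.warn(f"speed model not fitted: {exc}", stacklevel=2)

    if len(precision):
        prec = precision.copy()
        prec["unavailable_encountered"] = prec["frog_id"].map(unavailable).astype(float)
        for phase, responses in (
            ("TT", {"sc": "beta", "mean_ang_dev_deg": "gamma", "mean_perp_dev_m": "gamma"}),
            ("HT", {"sc": "beta", "mean_ang_dev_deg": "gaussian", "mean_perp_dev_m": "gaussian"}),
        ):
            sub = prec[prec["phase"] == phase]
            if sub["frog_id"].nunique() < 3 or sub["unavailable_encountered"].nunique() < 2:
                continue
            for resp, family in responses.items():
                try:
                    full = fit_mixed_model(
                        ModelSpec(resp, family=family, fixed_terms=("unavailable_encountered",)),
                        sub,
                    )
                    null = fit_mixed_model(ModelSpec(resp, family=family), sub)
                    out[f"{phase}_{resp}_vs_availability"] = {
                        "full": full,
                        "null": null,
                        **compare_to_null(full, null),
                    }
                except (ValidationError, np.linalg.LinAlgError) as exc:
                    warnings.warn(f"{phase} {resp} model not fitted: {exc}", stacklevel=2)
    return out


def weather_speed_selection(
    fixes_by_frog: dict[str, pd.DataFrame],
    covariates: pd.DataFrame,
    window: DaylightWindow = DaylightWindow(),
):
    """All-subset selection of weather effects on per-interval speed.

    Per-3h-interval speeds (distance moved within the interval over its
    covered duration) are merged with the interval weather series
    (temperature, cumulative rain) and modelled with a gamma GLMM (log link,
    frog identity as random intercept); every subset of {tadpoles present,
    time of day, temperature, rain} is ranked by AICc and the Delta <= 2
    subset is model-averaged.  Returns the
    :class:`tadtraj.models.SelectionResult`.
    """
    from .core import interval_speeds
    from .models import all_subset_selection

    tables = [interval_speeds(df, window) for df in fixes_by_frog.values()]
    speeds = pd.concat([t for t in tables if len(t)], ignore_index=True)
    data = speeds.merge(covariates, on=["date", "interval_start_h"], how="inner")
    data = data[(data["speed_m_per_h"] > 0) & data["tadpoles_present"].notna()]
    data["time_of_day"] = data["interval_start_h"].astype(str)
    spec = ModelSpec("speed_m_per_h", family="gamma")
    return all_subset_selection(
        spec, ("tadpoles_present", "time_of_day", "temperature_c", "rain_mm"), data
    )


def run_analyze(cfg: RunConfig) -> AnalysisResult:
    """File-based analysis runner; writes the output bundle to
    ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixes = read_fixes(cfg.fixes_path, schema=cfg.column_map)
    pools = read_pools(cfg.pools_path)
    if cfg.territories_path:
        territories = territory_centers(read_territories(cfg.territories_path))
    else:
        raise ValidationError("a territory table is required")
    result = analyze(
        fixes,
        pools,
        territories,
        r_visit=cfg.r_visit,
        r_home=cfg.r_home,
        min_locations=cfg.min_locations,
        fit_models=cfg.fit_models,
    )
    result.table_tt.to_csv(out / "transport_summary.csv", index=False)
    result.table_ht.to_csv(out / "homing_summary.csv", index=False)
    result.precision.to_csv(out / "precision.csv", index=False)
    result.visit_table.to_csv(out / "visits.csv", index=False)

    model_rows = []
    for name, m in result.models.items():
        model_rows.append(
            {
                "model": name,
                "aicc_full": m["full"].aicc,
                "aicc_null": m["null"].aicc,
                "delta_aicc": m["delta_aicc"],
                "verdict": m["verdict"],
                "n": m["full"].n,
                "converged": int(m["full"].converged and m["null"].converged),
            }
        )
    pd.DataFrame(
        model_rows,
        columns=["model", "aicc_full", "aicc_null", "delta_aicc", "verdict", "n", "converged"],
    ).to_csv(out / "model_comparison.csv", index=False)

    log = {
        "tadtraj_version": __version__,
        "config": {
            k: v for k, v in dataclasses.asdict(cfg).items() if not k.startswith("_")
        },
        "n_frogs": len(fixes),
        "n_segmented": len(result.trajectories),
        "visit_stats": result.visit_stats,
        "rayleigh": {
            ph: {"n": r.n, "rbar": r.rbar, "z": r.z, "p": r.p}
            for ph, r in result.rayleigh.items()
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return result


def run_simulate(cfg: SimConfig, out_dir) -> dict:
    """Simulate a study and write the fixture bundle (fixes, pools,
    territories, ground truth, manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pools, territories, fixes, truths = simulate_study(cfg)
    if fixes:
        write_fixes(fixes, out / "fixes.csv")
    else:
        pd.DataFrame(columns=["frog_id", "timestamp", "x_m", "y_m", "tadpoles", "behavior"]).to_csv(
            out / "fixes.csv", index=False
        )
    write_pools(pools, out / "pools.csv")
    terr_rows = [
        {
            "frog_id": t.frog_id,
            "timestamp": "2015-01-20T09:00:00",
            "x_m": t.center[0],
            "y_m": t.center[1],
            "territorial": 1,
        }
        for t in territories.values()
    ]
    pd.DataFrame(
        terr_rows, columns=["frog_id", "timestamp", "x_m", "y_m", "territorial"]
    ).to_csv(out / "territories.csv", index=False)
    truth_json = {
        fid: {
            "itinerary": t.itinerary,
            "deposits": t.deposits,
            "initial_load": t.initial_load,
            "states": t.states,
            "phases": t.phases,
            "pre_encounter_path_m": t.pre_encounter_path_m,
            "kappa": t.kappa,
            "speed_ratio_tt": t.speed_ratio_tt,
            "complete": t.complete,
        }
        for fid, t in truths.items()
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=2, sort_keys=True))
    manifest = {"tadtraj_version": __version__, "sim_config": dataclasses.asdict(cfg)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"n_frogs": len(fixes), "n_pools": len(pools), "out_dir": str(out)}
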