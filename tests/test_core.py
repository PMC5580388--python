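"""Core trajectory accounting: I/O, segmentation, distances, durations,
speeds."""

import numpy as np
import pandas as pd
import pytest

from tadtraj.core import (
    DaylightWindow,
    SchemaError,
    Territory,
    ValidationError,
    active_duration,
    elapsed_active_hours,
    interpolate_start,
    mean_speed,
    path_length,
    read_fixes,
    segment_phases,
    step_speeds,
    territory_center,
    write_fixes,
)
from tadtraj.pools import VisitEvent

from conftest import make_trajectory


# ---------------------------------------------------------------------------
# I/O


def _fix_frame(n, frog="F00", t0="2015-02-01 08:00", dx=3.0):
    t = pd.date_range(t0, periods=n, freq="45min")
    return pd.DataFrame(
        {
            "frog_id": frog,
            "timestamp": t,
            "x_m": np.arange(n) * dx + 100.0,
            "y_m": np.arange(n) * 0.5 + 200.0,
            "tadpoles": [8.0] * (n - 1) + [np.nan],
            "behavior": ["transport"] * (n - 1) + ["unknown"],
        }
    )


def test_read_fixes_identity(tmp_path):
    df = _fix_frame(3)
    path = tmp_path / "fixes.csv"
    write_fixes(df, path)
    out = read_fixes(path)
    assert list(out) == ["F00"]
    assert len(out["F00"]) == 3


def test_read_fixes_roundtrip_100(tmp_path, rng):
    n = 100
    df = _fix_frame(n)
    df["x_m"] = rng.normal(500, 40, n)
    df["y_m"] = rng.normal(800, 40, n)
    path = tmp_path / "fixes.csv"
    write_fixes(df, path)
    back = read_fixes(path)["F00"]
    np.testing.assert_allclose(back["x_m"], df["x_m"], rtol=0, atol=1e-9)
    np.testing.assert_allclose(back["y_m"], df["y_m"], rtol=0, atol=1e-9)
    assert (back["timestamp"] == df["timestamp"]).all()
    assert back["tadpoles"].iloc[0] == 8.0 and np.isnan(back["tadpoles"].iloc[-1])
    assert back["behavior"].iloc[-1] == "unknown"


def test_read_fixes_out_of_order_rejected(tmp_path):
    df = _fix_frame(4)
    df.loc[2, "timestamp"] = df.loc[0, "timestamp"]  # duplicate after sorting
    path = tmp_path / "bad.csv"
    write_fixes(df, path)
    with pytest.raises(ValidationError, match="non-increasing"):
        read_fixes(path)


def test_read_fixes_missing_column_named(tmp_path):
    df = _fix_frame(3).drop(columns=["x_m"])
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="x_m"):
        read_fixes(path)


def test_read_fixes_refuses_lonlat(tmp_path):
    df = _fix_frame(3)
    df["x_m"] = [-52.58, -52.581, -52.582]
    df["y_m"] = [3.99, 3.991, 3.992]
    path = tmp_path / "deg.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValidationError, match="project"):
        read_fixes(path)


def test_read_fixes_tadpole_bound(tmp_path):
    df = _fix_frame(3)
    df["tadpoles"] = [30.0, 30.0, 30.0]
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValidationError, match="tadpole"):
        read_fixes(path)


def test_read_fixes_column_map(tmp_path):
    df = _fix_frame(3).rename(columns={"x_m": "X", "timestamp": "time"})
    path = tmp_path / "mapped.csv"
    df.to_csv(path, index=False)
    out = read_fixes(path, schema={"x_m": "X", "timestamp": "time"})
    assert len(out["F00"]) == 3


# ---------------------------------------------------------------------------
# Territory center


def test_territory_center_centroid():
    t = territory_center([(0, 0), (2, 0), (1, 3)], [True, True, True])
    np.testing.assert_allclose(t.center, [1.0, 1.0])
    assert t.n_captures == 3


def test_territory_center_uses_only_territorial_captures():
    pts = [(5, 5)] + [(100, 100)] * 5
    flags = [True] + [False] * 5
    t = territory_center(pts, flags)
    np.testing.assert_allclose(t.center, [5.0, 5.0])
    assert t.n_captures == 1


def test_territory_center_requires_territorial():
    with pytest.raises(ValidationError, match="no territorial captures"):
        territory_center([(0, 0)], [False])


def test_territory_center_law_of_large_numbers(rng):
    pts = rng.normal([10, 20], 1.0, size=(200, 2))
    t = territory_center(pts, np.ones(200, dtype=bool))
    assert np.hypot(*(t.center - [10, 20])) < 0.3


# ---------------------------------------------------------------------------
# Distances


def test_path_length_collinear():
    assert path_length([(0, 0), (1, 0), (2, 0)]) == pytest.approx(2.0)


def test_path_length_three_four_five():
    assert path_length([(0, 0), (3, 0), (3, 4)]) == pytest.approx(7.0)


def test_path_length_matches_bruteforce(rng):
    for _ in range(50):
        xy = rng.normal(0, 30, size=(50, 2))
        brute = sum(
            float(np.sqrt((xy[i + 1, 0] - xy[i, 0]) ** 2 + (xy[i + 1, 1] - xy[i, 1]) ** 2))
            for i in range(len(xy) - 1)
        )
        assert abs(path_length(xy) - brute) < 1e-9


def test_path_length_chord_inequality(rng):
    # equality iff collinear and monotone along the chord
    collinear = np.array([(0.0, 0.0), (1.0, 1.0), (3.0, 3.0)])
    chord = float(np.hypot(*(collinear[-1] - collinear[0])))
    assert path_length(collinear) == pytest.approx(chord)
    for _ in range(20):
        xy = rng.normal(0, 10, size=(12, 2))
        chord = float(np.hypot(*(xy[-1] - xy[0])))
        assert path_length(xy) >= chord - 1e-12


def test_path_length_needs_two_fixes():
    with pytest.raises(ValidationError):
        path_length([(0, 0)])


# ---------------------------------------------------------------------------
# Interpolated start


def test_interpolate_start_chord():
    t = Territory("F00", np.array([0.0, 0.0]), 3)
    assert interpolate_start(t, (3, 4)) == pytest.approx(5.0)
    assert interpolate_start(t, (0, 0)) == pytest.approx(0.0)


def test_interpolate_start_is_minimum_distance(rng):
    # chord never exceeds the true pre-encounter walk length
    for _ in range(100):
        center = rng.normal(0, 5, 2)
        steps = rng.normal(0, 2, size=(10, 2))
        walk = center + np.cumsum(steps, axis=0)
        true_len = path_length(np.vstack([center, walk]))
        t = Territory("F00", center, 1)
        assert interpolate_start(t, walk[-1]) <= true_len + 1e-12


# ---------------------------------------------------------------------------
# Durations and speeds


def test_active_duration_same_day():
    traj = make_trajectory([(0, 0), (10, 0)], times=["2015-02-01 09:00", "2015-02-01 14:00"])
    assert active_duration(traj) == pytest.approx(5.0)


def test_active_duration_one_night():
    traj = make_trajectory([(0, 0), (10, 0)], times=["2015-02-01 10:00", "2015-02-02 10:00"])
    assert active_duration(traj) == pytest.approx(12.0)


def _daylight_overlap_hours(t0, t1, window=DaylightWindow()):
    """Brute-force oracle: sum of per-day overlap with the daylight window."""
    t0, t1 = pd.Timestamp(t0), pd.Timestamp(t1)
    total = 0.0
    day = t0.normalize()
    while day <= t1.normalize():
        lo = max(t0, day + pd.Timedelta(hours=window.day_start.hour))
        hi = min(t1, day + pd.Timedelta(hours=window.day_end.hour))
        total += max((hi - lo).total_seconds(), 0.0) / 3600.0
        day += pd.Timedelta(days=1)
    return total


def test_active_duration_two_nights_vs_bruteforce():
    traj = make_trajectory(
        [(0, 0), (10, 0)], times=["2015-02-01 18:00", "2015-02-03 08:00"]
    )
    assert active_duration(traj) == pytest.approx(14.0)
    assert active_duration(traj) == pytest.approx(
        _daylight_overlap_hours("2015-02-01 18:00", "2015-02-03 08:00")
    )


def test_elapsed_active_hours_matches_bruteforce(rng):
    base = pd.Timestamp("2015-02-01")
    for _ in range(50):
        d0, d1 = sorted(rng.integers(0, 5, 2))
        h0 = rng.uniform(7, 19)
        h1 = rng.uniform(7, 19)
        t0 = base + pd.Timedelta(days=int(d0), hours=float(h0))
        t1 = base + pd.Timedelta(days=int(d1), hours=float(h1))
        if t1 <= t0:
            t0, t1 = t1, t0
        assert elapsed_active_hours(t0, t1) == pytest.approx(
            _daylight_overlap_hours(t0, t1), abs=1e-9
        )


def test_active_duration_clamps_night_fix():
    traj = make_trajectory(
        [(0, 0), (10, 0)], times=["2015-02-01 06:30", "2015-02-01 12:00"]
    )
    with pytest.warns(UserWarning, match="clamped"):
        hours = active_duration(traj)
    assert hours == pytest.approx(5.0)


def test_mean_speed_worked_examples():
    # 55.16 m over 3.08 h and 22.16 m over 1 h
    traj = make_trajectory(
        [(0, 0), (55.16, 0)], times=["2015-02-01 09:00:00", "2015-02-01 12:04:48"]
    )
    assert mean_speed(traj) == pytest.approx(17.91, abs=0.005)
    traj2 = make_trajectory(
        [(0, 0), (22.16, 0)], times=["2015-02-01 09:00", "2015-02-01 10:00"]
    )
    assert mean_speed(traj2) == pytest.approx(22.16)


def test_mean_speed_uses_path_not_displacement():
    # closed loop of length 10 m in 2 h
    sq = [(0, 0), (2.5, 0), (2.5, 2.5), (0, 2.5), (0, 0)]
    traj = make_trajectory(sq, step_minutes=30)
    assert mean_speed(traj) == pytest.approx(5.0)


def test_step_speeds_basic():
    traj = make_trajectory([(0, 0), (10, 0)], step_minutes=30)
    np.testing.assert_allclose(step_speeds(traj), [20.0])


def test_step_speeds_stationary_zero():
    traj = make_trajectory([(5, 5)] * 4, step_minutes=45)
    np.testing.assert_allclose(step_speeds(traj), [0.0, 0.0, 0.0])


def test_step_speeds_duplicate_timestamp_rejected():
    traj = make_trajectory(
        [(0, 0), (1, 0), (2, 0)],
        times=["2015-02-01 09:00", "2015-02-01 09:00", "2015-02-01 10:00"],
    )
    with pytest.raises(ValidationError):
        step_speeds(traj)


def test_step_speeds_night_excluded():
    # 12 m step from 18:00 to 08:00 next day = 2 active hours -> 6 m/h
    traj = make_trajectory(
        [(0, 0), (12, 0)], times=["2015-02-01 18:00", "2015-02-02 08:00"]
    )
    np.testing.assert_allclose(step_speeds(traj), [6.0])


def test_mean_speed_rigid_motion_invariant(rng):
    xy = rng.normal(0, 20, size=(15, 2))
    traj = make_trajectory(xy)
    ref = mean_speed(traj)
    th = 0.83
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    moved = xy @ R.T + np.array([310.0, -120.0])
    assert mean_speed(make_trajectory(moved)) == pytest.approx(ref, rel=1e-9)


def test_duration_additive_over_phase_split(rng):
    xy = rng.normal(0, 20, size=(11, 2))
    times = pd.date_range("2015-02-01 08:00", periods=11, freq="50min")
    full = make_trajectory(xy, times=times)
    a = make_trajectory(xy[:6], times=times[:6])
    b = make_trajectory(xy[5:], times=times[5:])
    assert active_duration(a) + active_duration(b) == pytest.approx(
        active_duration(full), abs=1 / 3600
    )


def test_interval_speeds_apportions_across_intervals():
    from tadtraj.core import interval_speeds

    df = pd.DataFrame(
        {
            "frog_id": "F00",
            "timestamp": pd.to_datetime(["2015-02-01 09:00", "2015-02-01 11:00"]),
            "x_m": [0.0, 12.0],
            "y_m": 0.0,
            "tadpoles": [5.0, 5.0],
            "behavior": "unknown",
        }
    )
    t = interval_speeds(df)
    # 12 m over 09:00-11:00 splits evenly between the 07-10 and 10-13 blocks
    assert list(t["interval_start_h"]) == [7.0, 10.0]
    np.testing.assert_allclose(t["distance_m"], [6.0, 6.0])
    np.testing.assert_allclose(t["speed_m_per_h"], [6.0, 6.0])
    np.testing.assert_allclose(t["hours"], [1.0, 1.0])
    assert (t["tadpoles_present"] == 1.0).all()


def test_interval_speeds_total_conserved(rng):
    from tadtraj.core import interval_speeds, path_length

    n = 12
    times = pd.date_range("2015-02-01 08:10", periods=n, freq="55min")
    xy = np.cumsum(rng.normal(0, 4, size=(n, 2)), axis=0)
    df = pd.DataFrame(
        {
            "frog_id": "F00",
            "timestamp": times,
            "x_m": xy[:, 0],
            "y_m": xy[:, 1],
            "tadpoles": 3.0,
            "behavior": "unknown",
        }
    )
    t = interval_speeds(df)
    assert t["distance_m"].sum() == pytest.approx(path_length(xy))
    assert t["hours"].sum() == pytest.approx(active_duration(make_trajectory(xy, times=times)))


# ---------------------------------------------------------------------------
# Phase segmentation


def _visit(frog, pool, t, status="available", dep=True, x=0.0, y=0.0):
    return VisitEvent(
        frog_id=frog,
        pool_id=pool,
        t_arrive=pd.Timestamp(t),
        t_depart=pd.Timestamp(t),
        status_at_visit=status,
        x=x,
        y=y,
        deposition=dep,
    )


def _track(n=10):
    # 10 m fix spacing: only the final fix falls within r_home of a territory
    # placed at the track end
    t = pd.date_range("2015-02-01 08:00", periods=n, freq="1h")
    return pd.DataFrame(
        {
            "frog_id": "F00",
            "timestamp": t,
            "x_m": np.arange(n) * 10.0,
            "y_m": 0.0,
            "tadpoles": np.nan,
            "behavior": "unknown",
        }
    )


def test_segment_single_deposition_shares_split_fix():
    fixes = _track(10)
    terr = Territory("F00", np.array([90.0, 0.0]), 2)
    v = _visit("F00", "P01", fixes["timestamp"][5], x=50.0, y=0.0)
    tt, ht = segment_phases(fixes, [v], terr)
    assert len(tt.fixes) == 6 and len(ht.fixes) == 5
    assert tt.fixes["timestamp"].iloc[-1] == ht.fixes["timestamp"].iloc[0]
    assert tt.phase == "TT" and ht.phase == "HT"
    np.testing.assert_allclose(tt.waypoints[-1], [50.0, 0.0])
    np.testing.assert_allclose(ht.waypoints[-1], terr.center)


def test_segment_ends_at_last_deposition():
    fixes = _track(10)
    terr = Territory("F00", np.array([90.0, 0.0]), 2)
    v1 = _visit("F00", "P01", fixes["timestamp"][3], x=30.0, y=0.0)
    v2 = _visit("F00", "P02", fixes["timestamp"][6], x=60.0, y=0.0)
    tt, _ = segment_phases(fixes, [v1, v2], terr)
    assert len(tt.fixes) == 7
    # waypoint chain: first fix, then both pools in visit order
    assert tt.waypoints.shape == (3, 2)
    np.testing.assert_allclose(tt.waypoints[1], [30.0, 0.0])


def test_segment_requires_deposition():
    fixes = _track(6)
    terr = Territory("F00", np.array([50.0, 0.0]), 2)
    v = _visit("F00", "P01", fixes["timestamp"][3], status="removed", dep=False, x=30, y=0)
    with pytest.raises(ValidationError, match="deposition"):
        segment_phases(fixes, [v], terr)


def test_segment_marks_incomplete_homing():
    fixes = _track(10)
    terr = Territory("F00", np.array([500.0, 500.0]), 2)  # never reached
    v = _visit("F00", "P01", fixes["timestamp"][5], x=25.0, y=0.0)
    _, ht = segment_phases(fixes, [v], terr)
    assert not ht.complete
    assert len(ht.fixes) == 5  # not silently truncated
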