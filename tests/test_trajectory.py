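"""Stay/move labelling, place clustering, event building/merging, home."""

import numpy as np
import pandas as pd
import pytest

from lifespace import geo
from lifespace.trajectory import (
    SegmentationConfig,
    build_events,
    cluster_stay_points,
    estimate_home,
    extract_trajectories,
    label_stay_move,
    merge_short_events,
)
from conftest import HOME, T0, WORK, fixes_frame, labeled_frame


def brute_force_labels(fixes, window_s=300.0, diag_threshold_m=100.0):
    """Independent stay/move oracle: evaluate every look-ahead window
    explicitly with plain Python loops."""
    t = [ts.timestamp() for ts in fixes["timestamp"]]
    lat = list(fixes["lat"])
    lon = list(fixes["lon"])
    n = len(t)
    stay = [False] * n
    for i in range(n):
        idx = [j for j in range(n) if t[i] <= t[j] < t[i] + window_s]
        la = [lat[j] for j in idx]
        lo = [lon[j] for j in idx]
        diag = geo.geodesic_distance(
            geo.GeoPoint(min(la), min(lo)), geo.GeoPoint(max(la), max(lo)))
        if diag <= diag_threshold_m:
            for j in idx:
                stay[j] = True
    return ["stay" if s else "move" for s in stay]


class TestLabelStayMove:
    def test_stationary_hour_is_all_stay(self):
        fixes = fixes_frame(np.arange(0, 60, 5), 55.7, 12.5)
        out = label_stay_move(fixes)
        assert (out["state"] == "stay").all()

    def test_steady_motion_is_move_except_trailing_window(self):
        # due east at 10 m/s, one fix per minute: every full window spans
        # ~3 km >> 100 m. Only the final fix, whose look-ahead window is a
        # singleton, degenerates to a zero-diagonal stay.
        speed_deg_per_min = 10 * 60 / (111_194.93)
        minutes = np.arange(12)
        fixes = fixes_frame(minutes, 0.0, minutes * speed_deg_per_min)
        out = label_stay_move(fixes)
        assert (out["state"].iloc[:-1] == "move").all()

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            n = int(rng.integers(2, 50))
            minutes = np.sort(rng.uniform(0, 120, n))
            lat = 55.7 + rng.normal(0, 0.002, n)
            lon = 12.5 + rng.normal(0, 0.002, n)
            fixes = fixes_frame(minutes, lat, lon)
            got = list(label_stay_move(fixes)["state"])
            assert got == brute_force_labels(fixes), f"trial {trial}"

    def test_transition_boundary_within_one_window(self, commute_day):
        fixes, truth = commute_day
        out = label_stay_move(fixes)
        move_minutes = (out.loc[out["state"] == "move", "timestamp"] - T0).dt.total_seconds() / 60
        first_move = move_minutes.min()
        assert truth["transitions_min"][0] - 5 <= first_move <= truth["transitions_min"][0] + 5

    def test_empty_input(self):
        out = label_stay_move(fixes_frame([], [], []))
        assert out.empty


class TestClusterStayPoints:
    def test_two_clumps_numbered_by_first_visit(self):
        rng = np.random.default_rng(5)
        jitter = lambda n: rng.normal(0, 5 / 111_194.93, n)  # ~5 m
        a = fixes_frame(np.arange(20), 55.7 + jitter(20), 12.5 + jitter(20))
        b = fixes_frame(np.arange(100, 120), 55.709 + jitter(20), 12.5 + jitter(20))
        lab = pd.concat([a, b], ignore_index=True)
        lab["state"] = "stay"
        lab["place_id"] = pd.array([pd.NA] * len(lab), dtype="Int64")
        lab["is_home"] = False
        out = cluster_stay_points(lab)
        assert set(out.loc[out.index < 20, "place_id"]) == {1}
        assert set(out.loc[out.index >= 20, "place_id"]) == {2}

    def test_sparse_stays_reclassified_as_move(self):
        lab = labeled_frame([("stay", pd.NA, [0, 200, 400], [55.7, 55.8, 55.9], [12.5, 12.6, 12.7])])
        out = cluster_stay_points(lab)
        assert (out["state"] == "move").all()
        assert out["place_id"].isna().all()

    def test_no_stays_passthrough(self):
        lab = labeled_frame([("move", pd.NA, [0, 5], [55.7, 55.8], [12.5, 12.6])])
        out = cluster_stay_points(lab)
        pd.testing.assert_frame_equal(out, lab)


class TestBuildEvents:
    def test_three_runs_three_events(self):
        lab = labeled_frame([
            ("stay", 1, np.arange(0, 40, 4), 55.70, 12.50),
            ("move", pd.NA, np.arange(40, 60, 4), 55.71, 12.51),
            ("stay", 2, np.arange(60, 100, 4), 55.72, 12.52),
        ])
        ev = build_events(lab)
        assert list(ev["kind"]) == ["stay", "move", "stay"]
        assert list(ev["seq"]) == [1, 2, 3]

    def test_run_crossing_midnight_splits(self):
        lab = labeled_frame([("stay", 1, np.arange(23 * 60, 25 * 60, 5), 55.7, 12.5)])
        ev = build_events(lab)
        assert len(ev) == 2
        assert ev["day"].iloc[0] != ev["day"].iloc[1]
        assert ev["end_utc"].iloc[0] == ev["start_utc"].iloc[1]

    def test_single_fix_run_zero_duration_retained(self):
        lab = labeled_frame([
            ("stay", 1, [0.0], 55.7, 12.5),
            ("move", pd.NA, [5.0, 10.0], 55.71, 12.51),
        ])
        ev = build_events(lab)
        assert len(ev) == 2
        assert ev["duration_min"].iloc[0] == 0.0

    def test_gap_over_hour_breaks_runs(self):
        lab = labeled_frame([
            ("stay", 1, np.arange(0, 30, 5), 55.7, 12.5),
            ("stay", 1, np.arange(120, 150, 5), 55.7, 12.5),
        ])
        ev = build_events(lab)
        assert len(ev) == 2  # same state+place, but the 90-min silence splits


class TestMergeShortEvents:
    cfg = SegmentationConfig(assign_gap_midpoints=False)

    def test_short_move_between_same_place_stays_dissolves(self):
        lab = labeled_frame([
            ("stay", 1, np.arange(0, 40, 4), 55.70, 12.50),
            ("move", pd.NA, [41.0, 43.0], 55.7005, 12.50),
            ("stay", 1, np.arange(44, 84, 4), 55.70, 12.50),
        ])
        ev = merge_short_events(build_events(lab, cfg=self.cfg), self.cfg)
        assert len(ev) == 1
        assert ev["kind"].iloc[0] == "stay"
        assert ev["duration_min"].iloc[0] == pytest.approx(80.0)
        assert ev["n_fixes"].iloc[0] == 22

    def test_short_stay_between_moves_dissolves(self):
        lab = labeled_frame([
            ("move", pd.NA, np.arange(0, 20, 4), 55.70 + np.arange(0, 20, 4) * 1e-3, 12.50),
            ("stay", 2, [21.0, 23.0], 55.72, 12.50),
            ("move", pd.NA, np.arange(24, 40, 4), 55.72 + np.arange(24, 40, 4) * 1e-3, 12.50),
        ])
        ev = merge_short_events(build_events(lab, cfg=self.cfg), self.cfg)
        assert list(ev["kind"]) == ["move"]
        assert ev["duration_min"].iloc[0] == pytest.approx(36.0)

    def test_all_long_events_fixed_point(self):
        lab = labeled_frame([
            ("stay", 1, np.arange(0, 40, 4), 55.70, 12.50),
            ("move", pd.NA, np.arange(40, 60, 4), 55.71, 12.51),
            ("stay", 2, np.arange(60, 100, 4), 55.72, 12.52),
        ])
        before = build_events(lab, cfg=self.cfg)
        after = merge_short_events(before, self.cfg)
        assert list(after["kind"]) == list(before["kind"])
        assert list(after["duration_min"]) == list(before["duration_min"])

    def test_no_adjacent_mergeable_events_after_merging(self):
        rng = np.random.default_rng(13)
        runs = []
        t = 0.0
        for k in range(12):
            dur = float(rng.uniform(2, 40))
            n = max(int(dur // 4), 1)
            if k % 2 == 0:
                runs.append(("stay", int(rng.integers(1, 3)), t + np.arange(n) * 4.0, 55.7, 12.5))
            else:
                runs.append(("move", pd.NA, t + np.arange(n) * 4.0, 55.71, 12.51))
            t += dur
        ev = merge_short_events(build_events(labeled_frame(runs), cfg=self.cfg), self.cfg)
        for a, b in zip(ev.itertuples(), ev.iloc[1:].itertuples()):
            if a.day != b.day:
                continue
            both_moves = a.kind == "move" and b.kind == "move"
            same_stay = (a.kind == "stay" and b.kind == "stay"
                         and pd.notna(a.place_id) and a.place_id == b.place_id)
            assert not (both_moves or same_stay)


class TestEstimateHome:
    def test_dominant_place_becomes_home(self, commute_day):
        fixes, _ = commute_day
        res = extract_trajectories(fixes)
        assert res.home is not None
        assert geo.geodesic_distance(res.home, geo.GeoPoint(*HOME)) < 5.0
        home_events = res.events[res.events["is_home"]]
        assert (home_events["kind"] == "stay").all()

    def test_two_nearby_places_both_flagged(self):
        # two stay clusters 60 m apart, both within 100 m of the modal cell
        rng = np.random.default_rng(21)
        j = lambda n: rng.normal(0, 2 / 111_194.93, n)
        d60 = 60 / 111_194.93
        lab = labeled_frame([
            ("stay", 1, np.arange(0, 100, 5), 55.7 + j(20), 12.5 + j(20)),
            ("stay", 2, np.arange(200, 300, 5), 55.7 + d60 + j(20), 12.5 + j(20)),
        ])
        ev = build_events(lab)
        home, ev2, lab2 = estimate_home(lab, ev)
        assert ev2["is_home"].all()
        assert 55.7 < home.lat < 55.7 + d60

    def test_all_moves_home_undefined(self):
        lab = labeled_frame([("move", pd.NA, np.arange(0, 100, 5),
                              55.7 + np.arange(0, 100, 5) * 1e-3, 12.5)])
        ev = build_events(lab)
        home, _, _ = estimate_home(lab, ev)
        assert home is None


class TestExtractTrajectories:
    def test_commute_day_recovers_five_events(self, commute_day):
        fixes, truth = commute_day
        res = extract_trajectories(fixes)
        ev = res.events
        assert list(ev["kind"]) == ["stay", "move", "stay", "move", "stay"]
        assert list(ev["is_home"]) == [True, False, False, False, True]
        assert ev["place_id"].iloc[0] == ev["place_id"].iloc[4]
        # transition times within one window of the designed schedule
        for k, tr in enumerate(truth["transitions_min"]):
            boundary = ev["end_utc"].iloc[k]
            got = (boundary - T0).total_seconds() / 60
            assert abs(got - tr) <= 5.0

    def test_all_day_at_home(self):
        fixes = fixes_frame(np.arange(0, 24 * 60, 5), 55.7, 12.5)
        res = extract_trajectories(fixes)
        assert len(res.events) == 1
        assert res.events["is_home"].iloc[0]

    def test_deterministic_rerun(self, commute_day):
        fixes, _ = commute_day
        a = extract_trajectories(fixes)
        b = extract_trajectories(fixes.copy())
        pd.testing.assert_frame_equal(a.events, b.events)
        pd.testing.assert_frame_equal(a.labeled, b.labeled)

    def test_every_surviving_fix_in_exactly_one_event(self, commute_day):
        fixes, _ = commute_day
        res = extract_trajectories(fixes)
        counts = {}
        for _, ev in res.events.iterrows():
            for f in ev["_fix_ids"]:
                counts[f] = counts.get(f, 0) + 1
        assert all(v == 1 for v in counts.values())
        assert len(counts) == res.labeled["event_id"].notna().sum()
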