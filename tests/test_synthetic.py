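"""The free-living simulator: determinism, schedule validity, renderers."""

import numpy as np
import pandas as pd
import pytest

from lifespace import geo
from lifespace.synthetic import (
    SimConfig,
    render_activity,
    render_gps,
    render_logsheet,
    render_steps,
    simulate_dataset,
    simulate_schedule,
    _position_at,
)

SMALL = SimConfig(n_subjects=2, n_days=3)


@pytest.fixture(scope="module")
def schedules():
    return simulate_schedule(SMALL, 42)


class TestSimulateSchedule:
    def test_seeded_reruns_identical(self):
        a = simulate_schedule(SMALL, 42)
        b = simulate_schedule(SMALL, 42)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.events, y.events)
            pd.testing.assert_frame_equal(x.true_daily, y.true_daily)

    def test_trip_counts_within_range(self, schedules):
        for sch in schedules:
            assert sch.true_daily["n_trips"].between(SMALL.trips_min, SMALL.trips_max).all()

    def test_days_tile_without_overlap(self, schedules):
        for sch in schedules:
            ev = sch.events
            assert (ev["start_utc"].iloc[1:].to_numpy() == ev["end_utc"].iloc[:-1].to_numpy()).all()
            by_day = ev.groupby(ev["start_utc"].dt.date)
            for _, grp in by_day:
                assert grp["kind"].iloc[0] == "stay" and grp["kind"].iloc[-1] == "stay"

    def test_durations_respect_minimums(self, schedules):
        for sch in schedules:
            ev = sch.events.copy()
            ev["dur"] = (ev["end_utc"] - ev["start_utc"]).dt.total_seconds() / 60
            assert (ev.loc[ev["kind"] == "move", "dur"] >= SMALL.min_trip_min - 1e-6).all()
            interior = ev.iloc[1:-1]
            stays = interior[interior["kind"] == "stay"]
            # midnight-adjacent home stays may be short on one side; interior
            # non-home stays must respect the minimum
            away = stays[~stays["is_home"].astype(bool)]
            assert (((away["end_utc"] - away["start_utc"]).dt.total_seconds() / 60)
                    >= SMALL.min_stay_min - 1e-6).all()

    def test_true_distance_round_trip_arithmetic(self):
        cfg = SimConfig(n_subjects=1, n_days=1, trips_min=2, trips_max=2)
        sch = simulate_schedule(cfg, 7)[0]
        ev = sch.events
        mid_place = ev[(ev["kind"] == "stay") & (ev["place_id"] != 1)]["place_id"].iloc[0]
        d = geo.geodesic_distance(sch.home, sch.places[int(mid_place)]) / 1e3
        assert sch.true_daily["distance_km"].iloc[0] == pytest.approx(2 * d, rel=1e-9)
        assert sch.true_daily["action_range_km"].iloc[0] == pytest.approx(d, rel=1e-9)

    def test_infeasible_config_raises(self):
        bad = SimConfig(n_subjects=1, n_days=1, trips_min=6, trips_max=6,
                        min_stay_min=300.0, max_stay_min=300.0)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_schedule(bad, 0)


class TestRenderGps:
    def test_noise_free_fixes_on_true_path(self, schedules):
        cfg = SimConfig(n_subjects=2, n_days=3, gps_noise_sd_m=0.0, indoor_dropout=0.0)
        sch = schedules[0]
        gps = render_gps(sch, cfg, 1)
        for _, fx in gps.sample(100, random_state=0).iterrows():
            lat, lon, _, _, _ = _position_at(sch, fx["timestamp"])
            d = geo.haversine_m(fx["lat"], fx["lon"], lat, lon)
            assert d < 1.0

    def test_full_indoor_dropout_leaves_only_moves(self, schedules):
        cfg = SimConfig(n_subjects=2, n_days=3, indoor_dropout=1.0)
        gps = render_gps(schedules[0], cfg, 2)
        for _, fx in gps.iterrows():
            _, _, kind, _, _ = _position_at(schedules[0], fx["timestamp"])
            assert kind == "move"

    def test_mean_sampling_interval(self, schedules):
        cfg = SimConfig(n_subjects=1, n_days=7, indoor_dropout=0.0)
        sch = simulate_schedule(cfg, 3)[0]
        gps = render_gps(sch, cfg, 3)
        mean_gap = gps["timestamp"].diff().dt.total_seconds().mean()
        assert mean_gap == pytest.approx(cfg.gps_mean_interval_s, rel=0.10)

    def test_accuracy_under_ceiling(self, schedules):
        gps = render_gps(schedules[0], SMALL, 4)
        assert (gps["accuracy_m"] <= 25.0).all()


class TestRenderActivity:
    def test_no_confusion_labels_equal_truth(self, schedules):
        cfg = SimConfig(n_subjects=2, n_days=3, mode_confusion={})
        act = render_activity(schedules[0], cfg, 5)
        for _, r in act.sample(100, random_state=0).iterrows():
            _, _, kind, _, mode = _position_at(schedules[0], r["timestamp"])
            expect = "still" if kind == "stay" else mode
            assert r["activity"] == expect

    def test_total_confusion_swaps_every_bicycle_move(self, schedules):
        cfg = SimConfig(n_subjects=2, n_days=3, mode_confusion={("bicycle", "vehicle"): 1.0})
        act = render_activity(schedules[0], cfg, 6)
        for _, r in act.iterrows():
            _, _, kind, _, mode = _position_at(schedules[0], r["timestamp"])
            if kind == "move" and mode == "bicycle":
                assert r["activity"] == "vehicle"

    def test_planted_rate_recovered(self):
        """~15% of bicycle/vehicle moves carry the swapped label."""
        cfg = SimConfig(n_subjects=10, n_days=10, modes=("bicycle", "vehicle"))
        swapped = total = 0
        for i, sch in enumerate(simulate_schedule(cfg, 11)):
            act = render_activity(sch, cfg, 100 + i)
            ev = sch.events
            for j, mv in ev[ev["kind"] == "move"].iterrows():
                sel = act[(act["timestamp"] >= mv["start_utc"]) & (act["timestamp"] < mv["end_utc"])]
                if sel.empty:
                    continue
                total += 1
                swapped += (sel["activity"].iloc[0] != mv["mode"])
        assert total >= 350  # a few short moves have no reading and are skipped
        assert swapped / total == pytest.approx(0.15, abs=0.04)


class TestRenderSteps:
    def test_no_activity_flat_counter(self, schedules):
        cfg = SimConfig(n_subjects=2, n_days=3, cadence_steps_per_min=0.0,
                        ambient_steps_per_hour=0.0, reboot_prob_per_day=0.0)
        st = render_steps(schedules[0], cfg, 8)
        assert (st["count"] == 0).all()

    def test_reboot_day_has_negative_diff(self, schedules):
        cfg = SimConfig(n_subjects=2, n_days=3, reboot_prob_per_day=1.0)
        st = render_steps(schedules[0], cfg, 9)
        assert (st["count"].diff() < 0).any()

    def test_walking_minutes_drive_counts(self):
        cfg = SimConfig(n_subjects=1, n_days=1, modes=("on_foot",),
                        ambient_steps_per_hour=0.0, reboot_prob_per_day=0.0,
                        place_max_km=2.0)
        sch = simulate_schedule(cfg, 13)[0]
        st = render_steps(sch, cfg, 14)
        walk_min = sch.true_daily["true_steps"].iloc[0] / cfg.cadence_steps_per_min
        assert st["count"].max() == pytest.approx(walk_min * 100, rel=0.02)


class TestRenderLogsheet:
    def test_fine_resolution_no_jitter_equals_truth_to_the_minute(self, schedules):
        log = render_logsheet(schedules[0], resolution_min=1.0, jitter_min=0.0)
        ev = schedules[0].events
        assert len(log) == len(ev)
        deltas = (log["start_utc"].to_numpy() - ev["start_utc"].to_numpy())
        assert np.abs(deltas / np.timedelta64(1, "s")).max() <= 30.0

    def test_rounding_to_quarter_hour(self, schedules):
        log = render_logsheet(schedules[0], resolution_min=15.0, jitter_min=0.0)
        offsets = (log["start_utc"].astype("int64") // 10**9) % (15 * 60)
        assert (offsets == 0).all()

    def test_jittered_times_within_bound(self, schedules):
        log = render_logsheet(schedules[0], resolution_min=15.0, jitter_min=15.0, seed=1)
        ev = schedules[0].events
        # every logged event's start differs from some true start by <= jitter + rounding
        for _, row in log.iterrows():
            deltas = (ev["start_utc"] - row["start_utc"]).dt.total_seconds().abs() / 60
            assert deltas.min() <= 15.0 + 7.5 + 1e-6


class TestSimulateDataset:
    def test_deterministic_and_complete(self):
        a = simulate_dataset(SMALL, 5)
        b = simulate_dataset(SMALL, 5)
        assert len(a) == SMALL.n_subjects
        for x, y in zip(a, b):
            for key in ("gps", "activity", "steps", "logsheet"):
                pd.testing.assert_frame_equal(x[key], y[key])
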