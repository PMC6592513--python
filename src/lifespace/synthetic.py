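"""Synthetic free-living data generator with ground truth.

Simulates subjects who live at a home location and make a few trips per day
to a small set of fixed places, then renders the sensor streams those days
would produce on a phone/watch setup:

* **GPS fixes** — exponential inter-arrival times (mean ~5 min), isotropic
  Gaussian position noise, an accuracy value under the 25 m ceiling, and a
  fraction of stay-time fixes deleted to mimic indoor signal loss;
* **activity-recognition readings** — one label per ~5 min (still during
  stays, the transport mode during moves) with integer confidences; an
  entire move's readings may carry a confused label (bicycle↔vehicle) with
  a configurable per-move probability;
* **step-counter readings** — a boot-cumulative register fed by walking
  cadence plus a small ambient rate during stays, reset to zero by random
  reboots;
* **log sheets** — the ground-truth schedule re-rendered at 15-min
  resolution with optional ±15-min reporting jitter, standing in for the
  participant-kept reference logs.

Every generator is a pure function of (schedule, config, seed); fixed seeds
reproduce byte-identical output. Moves follow straight lines between places
(no road network) — sufficient to exercise segmentation, clustering and
annotation, but not a model of real street geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import EARTH_RADIUS_M, GeoPoint, haversine_m

DAY_MIN = 24 * 60.0


@dataclass
class SimConfig:
    """Study-condition parameters of the simulator.

    Defaults mirror the free-living setting the pipeline targets: ~5-min
    irregular sampling, 10 m GPS noise under a 25 m accuracy ceiling, 10%
    indoor dropout, 2–6 trips of >= 10 min per day separated by stays of
    >= 30 min among up to 5 places within 10 km of home, bicycle↔vehicle
    label confusion at 0.15 per move, and step-counter reboots on 20% of
    days.
    """

    n_subjects: int = 5
    n_days: int = 7
    start_date: str = "2024-03-04"
    timezone: str = "UTC"

    trips_min: int = 2
    trips_max: int = 6
    min_stay_min: float = 30.0
    max_stay_min: float = 180.0
    min_trip_min: float = 10.0
    max_trip_min: float = 90.0
    day_start_hour_range: tuple[float, float] = (8.0, 11.0)

    n_places: int = 5
    place_min_km: float = 0.5
    place_max_km: float = 10.0
    region_lat: float = 55.70
    region_lon: float = 12.55

    modes: tuple[str, ...] = ("on_foot", "bicycle", "vehicle")
    mode_speeds: dict = field(default_factory=lambda: {"on_foot": 1.4, "bicycle": 4.5, "vehicle": 12.0})

    gps_mean_interval_s: float = 300.0
    gps_noise_sd_m: float = 10.0
    gps_accuracy_range_m: tuple[float, float] = (3.0, 25.0)
    indoor_dropout: float = 0.10

    activity_interval_s: float = 300.0
    confidence_range: tuple[int, int] = (50, 100)
    mode_confusion: dict = field(default_factory=lambda: {("bicycle", "vehicle"): 0.15, ("vehicle", "bicycle"): 0.15})

    cadence_steps_per_min: float = 100.0
    ambient_steps_per_hour: float = 60.0
    step_mean_interval_s: float = 300.0
    reboot_prob_per_day: float = 0.2

    def __post_init__(self) -> None:
        if not (0 <= self.indoor_dropout <= 1 and 0 <= self.reboot_prob_per_day <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(v <= 0 for v in self.mode_speeds.values()):
            raise ValueError("mode speeds must be positive")
        if self.trips_min < 1 or self.trips_max < self.trips_min:
            raise ValueError("invalid trips range")


@dataclass
class GroundTruthSchedule:
    """One subject's true week: places, event timeline, and daily metrics."""

    subject: str
    home: GeoPoint
    places: dict[int, GeoPoint]  # place 1 is home
    events: pd.DataFrame  # kind, start_utc, end_utc, place_id, mode
    true_daily: pd.DataFrame  # per-day metrics computed analytically


def _offset_point(origin: GeoPoint, dist_m: float, bearing_rad: float) -> GeoPoint:
    dlat = dist_m * np.cos(bearing_rad) / EARTH_RADIUS_M
    dlon = dist_m * np.sin(bearing_rad) / (EARTH_RADIUS_M * np.cos(np.radians(origin.lat)))
    return GeoPoint(origin.lat + np.degrees(dlat), origin.lon + np.degrees(dlon))


def _trip_minutes(dist_m: float, speed: float, cfg: SimConfig) -> float:
    return max(dist_m / speed / 60.0, cfg.min_trip_min)


def _pick_mode(dist_m: float, cfg: SimConfig, rng: np.random.Generator) -> str:
    feasible = [m for m in cfg.modes if _trip_minutes(dist_m, cfg.mode_speeds[m], cfg) <= cfg.max_trip_min]
    if not feasible:
        feasible = [max(cfg.modes, key=lambda m: cfg.mode_speeds[m])]
    return feasible[rng.integers(len(feasible))]


def simulate_schedule(cfg: SimConfig, seed) -> list[GroundTruthSchedule]:
    """Draw ground-truth schedules for every subject.

    Each day starts and ends with a stay at home; trips chain through
    distinct non-home places with stay/trip durations respecting the
    configured minimums. Raises if the configuration cannot fit a day's
    stays and trips into 24 h.
    """
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp(cfg.start_date, tz=cfg.timezone).tz_convert("UTC")
    schedules = []
    for s in range(cfg.n_subjects):
        subject = f"s{s + 1:02d}"
        home = _offset_point(GeoPoint(cfg.region_lat, cfg.region_lon),
                             rng.uniform(0, 30_000), rng.uniform(0, 2 * np.pi))
        places = {1: home}
        for p in range(cfg.n_places):
            places[p + 2] = _offset_point(home,
                                          rng.uniform(cfg.place_min_km * 1e3, cfg.place_max_km * 1e3),
                                          rng.uniform(0, 2 * np.pi))
        ev_rows = []
        daily_rows = []
        for d in range(cfg.n_days):
            day_start = t0 + pd.Timedelta(days=d)
            chain, moves = _simulate_day(places, cfg, rng)
            # lay out the timeline
            dep_min = rng.uniform(*cfg.day_start_hour_range) * 60.0
            move_total = sum(m["duration_min"] for m in moves)
            budget = DAY_MIN - dep_min - cfg.min_stay_min - move_total
            n_mid = len(chain) - 2
            if budget < n_mid * cfg.min_stay_min:
                raise ValueError("infeasible SimConfig: stays and trips exceed 24 h")
            extra = rng.uniform(0, cfg.max_stay_min - cfg.min_stay_min, size=n_mid) if n_mid else np.array([])
            spare = budget - n_mid * cfg.min_stay_min
            if extra.sum() > spare:
                extra *= spare / extra.sum()
            mid_stays = cfg.min_stay_min + extra

            cursor = 0.0
            rows = [{"kind": "stay", "place_id": chain[0], "mode": None,
                     "start_min": 0.0, "end_min": dep_min}]
            cursor = dep_min
            for i, mv in enumerate(moves):
                rows.append({"kind": "move", "place_id": None, "mode": mv["mode"],
                             "start_min": cursor, "end_min": cursor + mv["duration_min"]})
                cursor += mv["duration_min"]
                if i < len(moves) - 1:
                    rows.append({"kind": "stay", "place_id": chain[i + 1], "mode": None,
                                 "start_min": cursor, "end_min": cursor + mid_stays[i]})
                    cursor += mid_stays[i]
            rows.append({"kind": "stay", "place_id": chain[-1], "mode": None,
                         "start_min": cursor, "end_min": DAY_MIN})

            for r in rows:
                ev_rows.append({
                    "kind": r["kind"], "place_id": r["place_id"], "mode": r["mode"],
                    "start_utc": day_start + pd.Timedelta(minutes=r["start_min"]),
                    "end_utc": day_start + pd.Timedelta(minutes=r["end_min"]),
                })
            daily_rows.append(_true_daily(day_start, rows, places, home, cfg))

        events = pd.DataFrame(ev_rows)
        events["place_id"] = events["place_id"].astype("Int64")
        events["is_home"] = (events["kind"] == "stay") & (events["place_id"] == 1)
        schedules.append(GroundTruthSchedule(
            subject=subject, home=home, places=places,
            events=events, true_daily=pd.DataFrame(daily_rows),
        ))
    return schedules


def _simulate_day(places: dict, cfg: SimConfig, rng: np.random.Generator):
    """Pick the day's stay chain (home ... home) and the moves linking it."""
    k = int(rng.integers(cfg.trips_min, cfg.trips_max + 1))
    others = [p for p in places if p != 1]
    chain = [1]
    for _ in range(k - 1):
        options = [p for p in others if p != chain[-1]]
        chain.append(int(options[rng.integers(len(options))]))
    chain.append(1)
    moves = []
    for a, b in zip(chain[:-1], chain[1:]):
        dist = haversine_m(places[a].lat, places[a].lon, places[b].lat, places[b].lon)
        mode = _pick_mode(float(dist), cfg, rng)
        moves.append({"mode": mode, "dist_m": float(dist),
                      "duration_min": _trip_minutes(float(dist), cfg.mode_speeds[mode], cfg)})
    return chain, moves


def _true_daily(day_start, rows, places, home, cfg: SimConfig) -> dict:
    stays = [r for r in rows if r["kind"] == "stay"]
    moves = [r for r in rows if r["kind"] == "move"]
    stay_pts = [places[r["place_id"]] for r in stays]
    dist_km = sum(
        float(haversine_m(a.lat, a.lon, b.lat, b.lon)) for a, b in zip(stay_pts[:-1], stay_pts[1:])
    ) / 1e3
    away = [r for r in rows if not (r["kind"] == "stay" and r["place_id"] == 1)]
    visited = {r["place_id"] for r in stays}
    action_km = max(
        (float(haversine_m(home.lat, home.lon, places[p].lat, places[p].lon)) for p in visited), default=0.0
    ) / 1e3
    walk_min = sum(r["end_min"] - r["start_min"] for r in moves if r["mode"] == "on_foot")
    stay_min = sum(r["end_min"] - r["start_min"] for r in stays)
    return {
        "day": day_start.date(),
        "n_trips": len(moves),
        "n_places": len(visited),
        "time_out_min": sum(r["end_min"] - r["start_min"] for r in away),
        "distance_km": dist_km,
        "action_range_km": action_km,
        "true_steps": walk_min * cfg.cadence_steps_per_min + stay_min / 60.0 * cfg.ambient_steps_per_hour,
    }


# ---------------------------------------------------------------------------
# renderers


def _position_at(schedule: GroundTruthSchedule, when: pd.Timestamp) -> tuple[float, float, str, object, object]:
    """True (lat, lon, kind, place_id, mode) at an instant."""
    ev = schedule.events
    idx = ev["start_utc"].searchsorted(when, side="right") - 1
    idx = int(np.clip(idx, 0, len(ev) - 1))
    row = ev.iloc[idx]
    if row["kind"] == "stay":
        p = schedule.places[int(row["place_id"])]
        return p.lat, p.lon, "stay", row["place_id"], None
    # interpolate between the flanking stays
    prev_place = schedule.places[int(ev.iloc[idx - 1]["place_id"])]
    next_place = schedule.places[int(ev.iloc[idx + 1]["place_id"])]
    frac = (when - row["start_utc"]) / (row["end_utc"] - row["start_utc"])
    frac = float(np.clip(frac, 0.0, 1.0))
    lat = prev_place.lat + frac * (next_place.lat - prev_place.lat)
    lon = prev_place.lon + frac * (next_place.lon - prev_place.lon)
    return lat, lon, "move", pd.NA, row["mode"]


def _poisson_times(start: pd.Timestamp, end: pd.Timestamp, mean_s: float, rng) -> pd.DatetimeIndex:
    total_s = (end - start).total_seconds()
    n_max = int(total_s / mean_s * 2 + 50)
    gaps = rng.exponential(mean_s, size=n_max)
    offsets = np.cumsum(gaps)
    offsets = offsets[offsets < total_s]
    return start + pd.to_timedelta(offsets, unit="s")


def render_gps(schedule: GroundTruthSchedule, cfg: SimConfig, seed) -> pd.DataFrame:
    """Noisy GPS fix stream for one subject (io location schema)."""
    rng = np.random.default_rng(seed)
    start = schedule.events["start_utc"].iloc[0]
    end = schedule.events["end_utc"].iloc[-1]
    times = _poisson_times(start, end, cfg.gps_mean_interval_s, rng)
    rows = []
    for ts in times:
        lat, lon, kind, _, _ = _position_at(schedule, ts)
        if kind == "stay" and rng.random() < cfg.indoor_dropout:
            continue
        noise = rng.normal(0.0, cfg.gps_noise_sd_m, size=2)
        lat += np.degrees(noise[0] / EARTH_RADIUS_M)
        lon += np.degrees(noise[1] / (EARTH_RADIUS_M * np.cos(np.radians(lat))))
        rows.append({
            "timestamp": ts, "lat": lat, "lon": lon,
            "accuracy_m": rng.uniform(*cfg.gps_accuracy_range_m),
            "device": "phone",
        })
    return pd.DataFrame(rows, columns=["timestamp", "lat", "lon", "accuracy_m", "device"])


def render_activity(schedule: GroundTruthSchedule, cfg: SimConfig, seed) -> pd.DataFrame:
    """Activity-recognition readings with per-move label confusion."""
    rng = np.random.default_rng(seed)
    ev = schedule.events
    # decide each move's observed label once, so a confused move is
    # consistently confused — the planted rate survives per-move aggregation
    observed_mode = {}
    for i, row in ev.iterrows():
        if row["kind"] != "move":
            continue
        label = row["mode"]
        for (src, dst), p in cfg.mode_confusion.items():
            if label == src and rng.random() < p:
                label = dst
                break
        observed_mode[i] = label

    start = ev["start_utc"].iloc[0]
    end = ev["end_utc"].iloc[-1]
    offset = rng.uniform(0, cfg.activity_interval_s)
    n = int((end - start).total_seconds() // cfg.activity_interval_s)
    times = start + pd.to_timedelta(offset + np.arange(n) * cfg.activity_interval_s, unit="s")
    rows = []
    for ts in times:
        idx = int(np.clip(ev["start_utc"].searchsorted(ts, side="right") - 1, 0, len(ev) - 1))
        row = ev.iloc[idx]
        label = "still" if row["kind"] == "stay" else observed_mode[ev.index[idx]]
        rows.append({
            "timestamp": ts, "activity": label,
            "confidence": int(rng.integers(cfg.confidence_range[0], cfg.confidence_range[1] + 1)),
        })
    return pd.DataFrame(rows, columns=["timestamp", "activity", "confidence"])


def render_steps(schedule: GroundTruthSchedule, cfg: SimConfig, seed, device: str = "phone") -> pd.DataFrame:
    """Boot-cumulative step-counter readings with random reboots."""
    rng = np.random.default_rng(seed)
    ev = schedule.events
    start = ev["start_utc"].iloc[0]
    end = ev["end_utc"].iloc[-1]

    # true cumulative steps as a piecewise-linear function of time
    bounds = [start] + list(ev["end_utc"])
    rates = []  # steps per second within each event
    for _, row in ev.iterrows():
        if row["kind"] == "move" and row["mode"] == "on_foot":
            rates.append(cfg.cadence_steps_per_min / 60.0)
        elif row["kind"] == "stay":
            rates.append(cfg.ambient_steps_per_hour / 3600.0)
        else:
            rates.append(0.0)
    cum_at_bound = np.concatenate([[0.0], np.cumsum([
        r * (b1 - b0).total_seconds() for r, b0, b1 in zip(rates, bounds[:-1], bounds[1:])
    ])])

    def true_steps(ts: pd.Timestamp) -> float:
        i = int(np.clip(ev["start_utc"].searchsorted(ts, side="right") - 1, 0, len(ev) - 1))
        return cum_at_bound[i] + rates[i] * (ts - ev["start_utc"].iloc[i]).total_seconds()

    reboots = []
    n_days = (end - start).days
    for d in range(n_days):
        if rng.random() < cfg.reboot_prob_per_day:
            reboots.append(start + pd.Timedelta(days=d) + pd.Timedelta(seconds=rng.uniform(0, 86_400)))
    reboots = sorted(reboots)

    times = _poisson_times(start, end, cfg.step_mean_interval_s, rng)
    rows = []
    for ts in times:
        last_boot = start
        for rb in reboots:
            if rb <= ts:
                last_boot = rb
        count = int(true_steps(ts) - true_steps(last_boot))
        rows.append({"timestamp": ts, "count": max(count, 0), "device": device})
    return pd.DataFrame(rows, columns=["timestamp", "count", "device"])


def render_logsheet(
    schedule: GroundTruthSchedule,
    resolution_min: float = 15.0,
    jitter_min: float = 0.0,
    seed=None,
) -> pd.DataFrame:
    """Reference log of the true schedule at log-sheet fidelity.

    Interior event boundaries are jittered by ``±jitter_min`` (uniform) and
    all boundaries rounded to the nearest ``resolution_min``; events whose
    rounded span collapses to zero vanish, as a hurried diarist would omit
    them. Day edges (midnights) stay fixed.
    """
    rng = np.random.default_rng(seed)
    ev = schedule.events
    rows = []
    for day, grp in ev.groupby(ev["start_utc"].dt.date, sort=True):
        bounds = list(grp["start_utc"]) + [grp["end_utc"].iloc[-1]]
        new_bounds = [bounds[0]]
        for b in bounds[1:-1]:
            j = b + pd.Timedelta(minutes=float(rng.uniform(-jitter_min, jitter_min))) if jitter_min else b
            new_bounds.append(j)
        new_bounds.append(bounds[-1])
        # keep ordering after jitter, then snap to the log-sheet grid
        vals = pd.Series(new_bounds).cummax()
        res = pd.Timedelta(minutes=resolution_min)
        snapped = [bounds[0]] + [v.round(res) for v in vals[1:-1]] + [bounds[-1]]
        for (s, e), (_, row) in zip(zip(snapped[:-1], snapped[1:]), grp.iterrows()):
            if e <= s:
                continue
            rows.append({
                "subject": schedule.subject, "day": day, "kind": row["kind"],
                "start_utc": s, "end_utc": e,
                "duration_min": (e - s).total_seconds() / 60.0,
                "place_id": row["place_id"], "mode": row["mode"],
                "is_home": bool(row["is_home"]),
            })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["place_id"] = out["place_id"].astype("Int64")
    return out


def simulate_dataset(cfg: SimConfig, seed) -> list[dict]:
    """Schedules plus all rendered streams for every subject.

    Returns one dict per subject with keys ``schedule``, ``gps``,
    ``activity``, ``steps``, ``logsheet``. Stream seeds are spawned from
    ``seed`` so each subject/stream is an independent reproducible draw.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sched_seed, *stream_seeds = root.spawn(1 + 4 * cfg.n_subjects)
    schedules = simulate_schedule(cfg, sched_seed)
    out = []
    for i, sch in enumerate(schedules):
        g, a, st, lg = stream_seeds[4 * i:4 * i + 4]
        out.append({
            "schedule": sch,
            "gps": render_gps(sch, cfg, g),
            "activity": render_activity(sch, cfg, a),
            "steps": render_steps(sch, cfg, st),
            "logsheet": render_logsheet(sch, resolution_min=15.0, jitter_min=15.0, seed=lg),
        })
    return out
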