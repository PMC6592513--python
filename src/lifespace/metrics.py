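"""Daily life-space mobility metrics.

Seven per-day measures are computed from the extracted trajectory, the fix
stream, and the home coordinate:

* **MCP area** (km²) — area of the minimum convex polygon around the day's
  fixes after trimming fixes whose distance to the daily centroid exceeds
  the 99% empirical quantile;
* **action range** (km) — maximum straight-line (great-circle) distance from
  home over all fixes belonging to the day's events;
* **distance covered** (km) — sum of great-circle distances between
  consecutive stay centroids. Note this deliberately measures place-to-place
  displacement, not raw path length, and so undercounts wandering within a
  trip;
* **time out of home** (min) — summed duration of all move events and stays
  away from home;
* **time moving** (min) — summed duration of move events;
* **places visited** — count of distinct place IDs among the day's stays
  (home included);
* **trips** — count of move events.

Days on which home is undefined report the home-dependent metrics (action
range, time out) as missing rather than zero, so that residual statistics
against reference logs are not biased.
"""

from __future__ import annotations

from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from . import geo
from .trajectory import TrajectoryResult

DAILY_COLUMNS = [
    "day", "mcp_km2", "action_range_km", "distance_km", "time_out_min",
    "time_moving_min", "n_places", "n_trips", "observed_min", "home_defined",
]


def mcp_area(lat, lon, quantile: float = 0.99) -> float:
    """Minimum-convex-polygon area (km²) of a fix cloud.

    Fixes farther from the centroid than the ``quantile``-level empirical
    distance are trimmed before the hull is taken. The quantile uses ceil
    (``method="higher"``) semantics, so small samples — where the 99th
    percentile rank rounds up to the maximum — retain every point.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size == 0:
        return 0.0
    c = geo.centroid(lat, lon)
    d = geo.haversine_m(lat, lon, c.lat, c.lon)
    cut = np.quantile(d, quantile, method="higher")
    keep = d <= cut
    x, y = geo.local_project(lat[keep], lon[keep], c)
    return geo.convex_hull_area(x, y) / 1e6


def _day_events(events: pd.DataFrame, day) -> pd.DataFrame:
    return events[events["day"] == day]


def _day_fix_ids(events: pd.DataFrame, day) -> list:
    ids: list = []
    for _, ev in _day_events(events, day).iterrows():
        ids.extend(ev.get("_fix_ids") or [])
    return ids


def action_range(events: pd.DataFrame, labeled: pd.DataFrame, home: geo.GeoPoint | None, day) -> float:
    """Max great-circle distance (km) from home over the day's event fixes."""
    if home is None:
        return float("nan")
    ids = _day_fix_ids(events, day)
    if not ids:
        return float("nan")
    pts = labeled.loc[ids]
    d = geo.haversine_m(pts["lat"], pts["lon"], home.lat, home.lon)
    return float(np.max(d)) / 1e3


def distance_covered(events: pd.DataFrame, day) -> float:
    """Sum of great-circle distances (km) between consecutive stay centroids."""
    stays = _day_events(events, day)
    stays = stays[stays["kind"] == "stay"].sort_values("start_utc")
    if len(stays) < 2:
        return 0.0
    lat = stays["centroid_lat"].to_numpy()
    lon = stays["centroid_lon"].to_numpy()
    return float(np.sum(geo.haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:]))) / 1e3


def time_out_of_home(events: pd.DataFrame, day, home_defined: bool = True) -> float:
    """Minutes in move events or stays away from home; NaN if home unknown."""
    if not home_defined:
        return float("nan")
    evs = _day_events(events, day)
    out = evs[(evs["kind"] == "move") | (~evs["is_home"].astype(bool))]
    return float(out["duration_min"].sum())


def time_moving(events: pd.DataFrame, day) -> float:
    """Minutes in move events."""
    evs = _day_events(events, day)
    return float(evs.loc[evs["kind"] == "move", "duration_min"].sum())


def places_visited(events: pd.DataFrame, day) -> int:
    """Distinct places visited (home included), counted once each."""
    evs = _day_events(events, day)
    return int(evs.loc[evs["kind"] == "stay", "place_id"].dropna().nunique())


def trips(events: pd.DataFrame, day) -> int:
    """Number of move events."""
    evs = _day_events(events, day)
    return int((evs["kind"] == "move").sum())


def daily_metrics(
    result: TrajectoryResult,
    timezone: str = "UTC",
    mcp_quantile: float = 0.99,
) -> pd.DataFrame:
    """Assemble the seven metrics for every calendar day with data.

    MCP uses all accuracy-filtered fixes whose local date is the day;
    the remaining metrics derive from the event sequence. ``observed_min``
    (total event-covered minutes) is a coverage diagnostic, not a metric.
    """
    events, labeled, home = result.events, result.labeled, result.home
    tz = ZoneInfo(timezone)
    if labeled.empty:
        return pd.DataFrame(columns=DAILY_COLUMNS)
    fix_day = labeled["timestamp"].dt.tz_convert(tz).dt.date
    days = sorted(set(fix_day) | (set(events["day"]) if not events.empty else set()))

    rows = []
    for day in days:
        sel = labeled[fix_day == day]
        rows.append({
            "day": day,
            "mcp_km2": mcp_area(sel["lat"].to_numpy(), sel["lon"].to_numpy(), mcp_quantile) if len(sel) else 0.0,
            "action_range_km": action_range(events, labeled, home, day),
            "distance_km": distance_covered(events, day),
            "time_out_min": time_out_of_home(events, day, home_defined=home is not None),
            "time_moving_min": time_moving(events, day),
            "n_places": places_visited(events, day),
            "n_trips": trips(events, day),
            "observed_min": float(_day_events(events, day)["duration_min"].sum()),
            "home_defined": home is not None,
        })
    return pd.DataFrame(rows, columns=DAILY_COLUMNS)


def period_mcp(labeled: pd.DataFrame, quantile: float = 0.99) -> float:
    """Whole-recording MCP area (km²) over every fix."""
    return mcp_area(labeled["lat"].to_numpy(), labeled["lon"].to_numpy(), quantile)
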