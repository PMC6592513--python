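"""Travel-trajectory extraction from GPS fixes.

The pipeline turns an accuracy-filtered, time-sorted fix stream into a
chronological per-day sequence of *stay* and *move* events:

1. **Stay/move labelling** — for every fix, the fixes in the 5 minutes ahead
   are bounded by a lat/lon rectangle; if the rectangle's diagonal stays
   under a distance threshold the whole window is stationary and every fix
   in it is labelled *stay* (a fix claimed by any stay window remains a
   stay); otherwise the anchor fix is a *move* point.
2. **Place clustering** — stay fixes are clustered with DBSCAN (haversine
   metric) into distinct places, numbered by first visit; sparse stay fixes
   that fall outside any cluster are noise and are reclassified as moves.
3. **Event building** — maximal runs of fixes sharing a state (and, for
   stays, a place) become events; runs are never bridged across data gaps
   longer than an hour, and events are split at local midnight so that daily
   metrics partition lived time.
4. **Short-event merging** — events shorter than a time threshold whose two
   neighbours are compatible (both moves, or both stays at the same place)
   dissolve into a single merged event; the pass repeats to a fixed point.
5. **Home estimation** — a preliminary home is the modal grid cell of all
   fixes; every place whose centroid lies within a radius of it is flagged
   home, and the final home coordinate is the centroid of all stay fixes at
   home places.

All timestamps are UTC; a per-subject IANA timezone governs the midnight
day split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from . import geo
from .io import filter_by_accuracy

logger = logging.getLogger(__name__)

EVENT_ORDER = [
    "event_id", "day", "seq", "kind", "start_utc", "end_utc", "duration_min",
    "place_id", "is_home", "centroid_lat", "centroid_lon", "n_fixes",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds of the trajectory-extraction pipeline.

    window_s
        Look-ahead horizon of the stay/move test, seconds. Matches the ~5-min
        sampling period of the location stream.
    diag_threshold_m
        Bounding-rectangle diagonal above which a window is travelling.
        100 m over 5 min is ~0.33 m/s sustained displacement — above GPS
        noise at a 25 m accuracy ceiling, below slow walking.
    cluster_eps_m, cluster_min_pts
        DBSCAN neighbourhood radius and density for place clustering; eps
        matches the accuracy ceiling, min_pts one ~25-min dwell at 5-min
        sampling.
    min_event_minutes
        Events shorter than this are merged away or dropped.
    home_radius_m
        Places within this distance of the modal cell count as home.
    grid_decimals
        Decimal places of the home-mode grid (4 ~ 11 m cells).
    max_gap_minutes
        Runs separated by a longer fix-free gap are never joined; the gap is
        unclassified time.
    accuracy_max_m
        Preprocessing accuracy ceiling applied by :func:`extract_trajectories`.
    assign_gap_midpoints
        Sparse sampling leaves a fix-free interval around every true
        transition; anchoring events to their first/last fix would censor
        that interval and systematically undercount away-from-home time.
        When true (default), each sub-hour inter-event gap is split at its
        midpoint between the two neighbouring events, an unbiased allocation
        of the unobserved interval.
    """

    window_s: float = 300.0
    diag_threshold_m: float = 100.0
    cluster_eps_m: float = 25.0
    cluster_min_pts: int = 5
    min_event_minutes: float = 5.0
    home_radius_m: float = 100.0
    grid_decimals: int = 4
    max_gap_minutes: float = 60.0
    accuracy_max_m: float = 25.0
    assign_gap_midpoints: bool = True

    def __post_init__(self) -> None:
        for name in ("window_s", "diag_threshold_m", "cluster_eps_m", "cluster_min_pts",
                     "min_event_minutes", "home_radius_m", "max_gap_minutes", "accuracy_max_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class TrajectoryResult:
    """Output of :func:`extract_trajectories`."""

    events: pd.DataFrame
    labeled: pd.DataFrame
    home: geo.GeoPoint | None


# ---------------------------------------------------------------------------
# 1. stay/move labelling


def label_stay_move(fixes: pd.DataFrame, cfg: SegmentationConfig | None = None) -> pd.DataFrame:
    """Label each fix *stay* or *move* from look-ahead bounding windows."""
    cfg = cfg or SegmentationConfig()
    out = fixes.reset_index(drop=True).copy()
    n = len(out)
    out["state"] = pd.Series(dtype=object)
    out["place_id"] = pd.array([pd.NA] * n, dtype="Int64")
    out["is_home"] = False
    if n == 0:
        return out

    t = out["timestamp"].astype("int64").to_numpy()  # ns
    lat = out["lat"].to_numpy()
    lon = out["lon"].to_numpy()
    horizon = np.int64(cfg.window_s * 1e9)
    ends = np.searchsorted(t, t + horizon, side="left")

    stay = np.zeros(n, dtype=bool)
    for i in range(n):
        j = ends[i]
        if geo.bounding_diagonal(lat[i:j], lon[i:j]) <= cfg.diag_threshold_m:
            stay[i:j] = True
    out["state"] = np.where(stay, "stay", "move")
    return out


# ---------------------------------------------------------------------------
# 2. place clustering


def cluster_stay_points(labeled: pd.DataFrame, cfg: SegmentationConfig | None = None) -> pd.DataFrame:
    """Cluster stay fixes into places; noise fixes become move points.

    Places are numbered 1..K by time of first visit. DBSCAN runs on the
    haversine metric so ``cluster_eps_m`` is a true ground distance.
    """
    cfg = cfg or SegmentationConfig()
    out = labeled.reset_index(drop=True).copy()
    mask = (out["state"] == "stay").to_numpy()
    if not mask.any():
        return out

    coords = np.radians(out.loc[mask, ["lat", "lon"]].to_numpy())
    db = DBSCAN(
        eps=cfg.cluster_eps_m / geo.EARTH_RADIUS_M,
        min_samples=cfg.cluster_min_pts,
        metric="haversine",
        algorithm="ball_tree",
    ).fit(coords)
    raw_labels = db.labels_

    # renumber clusters by first-visit time
    stay_times = out.loc[mask, "timestamp"].to_numpy()
    order: dict[int, int] = {}
    for lbl, ts in sorted(zip(raw_labels, stay_times), key=lambda p: p[1]):
        if lbl != -1 and lbl not in order:
            order[lbl] = len(order) + 1
    place_ids = np.array([order.get(l, 0) for l in raw_labels])

    idx = out.index[mask]
    noise = place_ids == 0
    out.loc[idx[noise], "state"] = "move"
    out.loc[idx[~noise], "place_id"] = place_ids[~noise]
    return out


# ---------------------------------------------------------------------------
# 3. event building


def _runs_to_events(labeled: pd.DataFrame, cfg: SegmentationConfig) -> pd.DataFrame:
    """Maximal runs of (state, place_id), broken at >max_gap fix gaps."""
    lab = labeled.reset_index(drop=True)
    n = len(lab)
    if n == 0:
        return pd.DataFrame(columns=["kind", "start_utc", "end_utc", "place_id",
                                     "centroid_lat", "centroid_lon", "n_fixes", "segment", "_fix_ids"])
    state = lab["state"].to_numpy()
    place = lab["place_id"].to_numpy(dtype=object)
    t = lab["timestamp"].astype("int64").to_numpy()
    gap_ns = np.int64(cfg.max_gap_minutes * 60e9)

    gap_break = np.zeros(n, dtype=bool)
    gap_break[1:] = np.diff(t) > gap_ns
    run_break = np.zeros(n, dtype=bool)
    run_break[1:] = (state[1:] != state[:-1]) | np.array(
        [not _same_place(place[i], place[i - 1]) for i in range(1, n)]
    )
    run_id = np.cumsum(gap_break | run_break)
    segment = np.cumsum(gap_break)

    rows = []
    for rid in np.unique(run_id):
        sel = run_id == rid
        sub = lab[sel]
        rows.append({
            "kind": sub["state"].iloc[0],
            "start_utc": sub["timestamp"].iloc[0],
            "end_utc": sub["timestamp"].iloc[-1],
            "place_id": sub["place_id"].iloc[0],
            "centroid_lat": float(sub["lat"].mean()),
            "centroid_lon": float(sub["lon"].mean()),
            "n_fixes": int(sel.sum()),
            "segment": int(segment[sel][0]),
            "_fix_ids": list(sub.index),
        })
    return pd.DataFrame(rows)


def _same_place(a, b) -> bool:
    if pd.isna(a) and pd.isna(b):
        return True
    if pd.isna(a) or pd.isna(b):
        return False
    return a == b


def _split_days(events: pd.DataFrame, labeled: pd.DataFrame | None, timezone: str) -> pd.DataFrame:
    """Split events at local midnight; assign day and per-day seq."""
    tz = ZoneInfo(timezone)
    pieces = []
    for _, ev in events.iterrows():
        start = ev["start_utc"]
        end = ev["end_utc"]
        bounds = [start]
        m = (start.tz_convert(tz) + pd.Timedelta(days=1)).normalize().tz_convert("UTC")
        while m < end:
            bounds.append(m)
            m = (m.tz_convert(tz) + pd.Timedelta(days=1)).normalize().tz_convert("UTC")
        bounds.append(end)
        for k in range(len(bounds) - 1):
            piece = dict(ev)
            piece["start_utc"], piece["end_utc"] = bounds[k], bounds[k + 1]
            if len(bounds) > 2 and labeled is not None:
                fid = ev["_fix_ids"]
                ts = labeled.loc[fid, "timestamp"]
                inside = [f for f, x in zip(fid, ts) if bounds[k] <= x <= bounds[k + 1]] \
                    if k == len(bounds) - 2 else [f for f, x in zip(fid, ts) if bounds[k] <= x < bounds[k + 1]]
                piece["_fix_ids"] = inside
                if inside:
                    piece["n_fixes"] = len(inside)
                    piece["centroid_lat"] = float(labeled.loc[inside, "lat"].mean())
                    piece["centroid_lon"] = float(labeled.loc[inside, "lon"].mean())
                else:
                    piece["n_fixes"] = 0
            pieces.append(piece)
    out = pd.DataFrame(pieces)
    if out.empty:
        return pd.DataFrame(columns=EVENT_ORDER + ["segment", "_fix_ids"])
    out = out[out["n_fixes"] > 0].reset_index(drop=True)
    out["day"] = [s.tz_convert(tz).date() for s in out["start_utc"]]
    out["duration_min"] = (out["end_utc"] - out["start_utc"]).dt.total_seconds() / 60.0
    out = out.sort_values(["start_utc"], kind="stable").reset_index(drop=True)
    out["seq"] = out.groupby("day", sort=False).cumcount() + 1
    out["event_id"] = np.arange(len(out))
    if "is_home" not in out.columns:
        out["is_home"] = False
    out["place_id"] = pd.array(out["place_id"], dtype="Int64")
    return out[EVENT_ORDER + ["segment", "_fix_ids"]]


def build_events(
    labeled: pd.DataFrame,
    timezone: str = "UTC",
    cfg: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Turn labelled fixes into a chronological per-day event sequence.

    Zero-duration single-fix events are retained here; the merging stage
    decides their fate.
    """
    cfg = cfg or SegmentationConfig()
    runs = _runs_to_events(labeled, cfg)
    return _split_days(runs, labeled, timezone)


# ---------------------------------------------------------------------------
# 4. short-event merging


def _unsplit_midnight(events: pd.DataFrame, timezone: str) -> pd.DataFrame:
    """Rejoin pieces that abut exactly at a midnight boundary (inverse of the
    day split) so merging sees whole events."""
    if events.empty:
        return events
    evs = events.sort_values("start_utc", kind="stable").reset_index(drop=True)
    rows = [dict(evs.iloc[0])]
    for i in range(1, len(evs)):
        cur = dict(evs.iloc[i])
        prev = rows[-1]
        joinable = (
            prev["end_utc"] == cur["start_utc"]
            and prev["kind"] == cur["kind"]
            and _same_place(prev["place_id"], cur["place_id"])
            and prev["segment"] == cur["segment"]
        )
        if joinable:
            rows[-1] = _combine(prev, cur)
        else:
            rows.append(cur)
    return pd.DataFrame(rows)


def _combine(a: dict, b: dict) -> dict:
    """Merge two chronologically adjacent events into one spanning both."""
    n = a["n_fixes"] + b["n_fixes"]
    out = dict(a)
    out["end_utc"] = b["end_utc"]
    if n > 0:
        out["centroid_lat"] = (a["centroid_lat"] * a["n_fixes"] + b["centroid_lat"] * b["n_fixes"]) / n
        out["centroid_lon"] = (a["centroid_lon"] * a["n_fixes"] + b["centroid_lon"] * b["n_fixes"]) / n
    out["n_fixes"] = n
    fa = a.get("_fix_ids") or []
    fb = b.get("_fix_ids") or []
    out["_fix_ids"] = list(fa) + list(fb)
    return out


def merge_short_events(
    events: pd.DataFrame,
    cfg: SegmentationConfig | None = None,
    timezone: str = "UTC",
    labeled: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Dissolve sub-threshold events between compatible neighbours.

    Iterates to a fixed point: the earliest event shorter than
    ``min_event_minutes`` whose neighbours are both moves, or both stays at
    the same place (and in the same contiguous data segment), is dissolved
    and its neighbours merged across the gap. Afterwards, still-short events
    at segment edges are dropped, events are re-split at local midnight and
    per-day sequence numbers reassigned.
    """
    cfg = cfg or SegmentationConfig()
    if events.empty:
        return events
    evs = _unsplit_midnight(events, timezone)
    rows = [dict(r) for _, r in evs.iterrows()]
    min_ns = pd.Timedelta(minutes=cfg.min_event_minutes)

    changed = True
    while changed:
        changed = False
        for i in range(1, len(rows) - 1):
            dur = rows[i]["end_utc"] - rows[i]["start_utc"]
            if dur >= min_ns:
                continue
            left, right = rows[i - 1], rows[i + 1]
            if left["segment"] != rows[i]["segment"] or right["segment"] != rows[i]["segment"]:
                continue
            mergeable = (
                left["kind"] == right["kind"]
                and (left["kind"] == "move" or _same_place(left["place_id"], right["place_id"]))
            )
            if mergeable:
                merged = _combine(_combine(left, rows[i]), right)
                merged["kind"] = left["kind"]
                merged["place_id"] = left["place_id"]
                rows[i - 1:i + 2] = [merged]
                changed = True
                break

    # drop still-short events at segment edges
    keep = []
    for i, r in enumerate(rows):
        dur = r["end_utc"] - r["start_utc"]
        at_edge = (
            i == 0 or i == len(rows) - 1
            or rows[i - 1]["segment"] != r["segment"]
            or rows[i + 1]["segment"] != r["segment"]
        )
        if dur < min_ns and at_edge:
            continue
        keep.append(r)

    if cfg.assign_gap_midpoints:
        for a, b in zip(keep[:-1], keep[1:]):
            if a["segment"] == b["segment"] and a["end_utc"] < b["start_utc"]:
                mid = a["end_utc"] + (b["start_utc"] - a["end_utc"]) / 2
                a["end_utc"] = mid
                b["start_utc"] = mid

    out = pd.DataFrame(keep)
    if out.empty:
        return _split_days(out, labeled, timezone)
    return _split_days(out.drop(columns=[c for c in ("day", "seq", "event_id", "duration_min") if c in out.columns]),
                       labeled, timezone)


# ---------------------------------------------------------------------------
# 5. home estimation


def estimate_home(
    labeled: pd.DataFrame,
    events: pd.DataFrame,
    cfg: SegmentationConfig | None = None,
) -> tuple[geo.GeoPoint | None, pd.DataFrame, pd.DataFrame]:
    """Estimate the home coordinate and flag home stays.

    Returns ``(home, events, labeled)`` with ``is_home`` filled in. When no
    stay fixes exist (or no place lies near the modal cell) home is ``None``
    and a warning is logged; home-dependent metrics are then undefined.
    """
    cfg = cfg or SegmentationConfig()
    events = events.copy()
    labeled = labeled.copy()
    events["is_home"] = False
    labeled["is_home"] = False

    stays = labeled[(labeled["state"] == "stay") & labeled["place_id"].notna()]
    if stays.empty:
        logger.warning("no stay fixes: home undefined, home-dependent metrics will be missing")
        return None, events, labeled

    prelim = geo.coordinate_mode(
        labeled["lat"].to_numpy(), labeled["lon"].to_numpy(),
        grid_decimals=cfg.grid_decimals,
        order=labeled["timestamp"].astype("int64").to_numpy(),
    )
    cent = stays.groupby("place_id")[["lat", "lon"]].mean()
    dists = geo.haversine_m(cent["lat"], cent["lon"], prelim.lat, prelim.lon)
    home_places = set(cent.index[np.asarray(dists) <= cfg.home_radius_m])
    if not home_places:
        logger.warning("no place near the modal cell: home undefined")
        return None, events, labeled

    home_fixes = stays[stays["place_id"].isin(home_places)]
    home = geo.centroid(home_fixes["lat"].to_numpy(), home_fixes["lon"].to_numpy())
    labeled.loc[labeled["place_id"].isin(home_places), "is_home"] = True
    events.loc[(events["kind"] == "stay") & events["place_id"].isin(home_places), "is_home"] = True
    return home, events, labeled


# ---------------------------------------------------------------------------
# composition


def extract_trajectories(
    fixes: pd.DataFrame,
    cfg: SegmentationConfig | None = None,
    timezone: str = "UTC",
) -> TrajectoryResult:
    """Full pipeline from raw fixes to the per-day stay/move event sequence.

    Deterministic for a fixed input and configuration.
    """
    cfg = cfg or SegmentationConfig()
    filtered = filter_by_accuracy(fixes, cfg.accuracy_max_m)
    labeled = label_stay_move(filtered, cfg)
    labeled = cluster_stay_points(labeled, cfg)
    events = build_events(labeled, timezone, cfg)
    events = merge_short_events(events, cfg, timezone, labeled)
    home, events, labeled = estimate_home(labeled, events, cfg)

    if not events.empty:
        fix_event = pd.Series(pd.NA, index=labeled.index, dtype="Int64")
        for _, ev in events.iterrows():
            for f in ev["_fix_ids"] or []:
                fix_event.loc[f] = ev["event_id"]
        labeled["event_id"] = fix_event
        events = events.drop(columns=["segment"])
    return TrajectoryResult(events=events, labeled=labeled, home=home)
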