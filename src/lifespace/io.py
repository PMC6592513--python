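"""Reading, validating, merging, and writing sensor log tables.

Input logs are delimited text with a header row. Column names and the
timestamp encoding are configurable through :class:`Dialect`; one dialect per
stream type. Three streams exist:

* location fixes — timestamp, latitude, longitude, horizontal accuracy (m),
  source device (watch/phone/unknown);
* activity-recognition readings — timestamp, activity label, confidence 0–100
  (several readings may share one timestamp);
* step-counter readings — timestamp, cumulative count since device boot,
  source device. Counts may drop across a reboot; that is handled downstream.

Rows violating value bounds (latitude outside ±90, confidence over 100,
negative step counts, …) are rejected, counted in ``df.attrs["n_rejected"]``
and logged — never silently dropped. An unparseable timestamp is a hard
error naming the offending row, since it usually means the dialect is wrong
for the whole file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOCATION_COLUMNS = ["timestamp", "lat", "lon", "accuracy_m", "device"]
ACTIVITY_COLUMNS = ["timestamp", "activity", "confidence"]
STEP_COLUMNS = ["timestamp", "count", "device"]
EVENT_COLUMNS = [
    "subject", "day", "seq", "kind", "start_utc", "end_utc", "duration_min",
    "place_id", "is_home", "centroid_lat", "centroid_lon", "n_fixes",
]

ACTIVITY_LABELS = {"still", "tilting", "on_foot", "walking", "running", "on_bicycle", "in_vehicle", "unknown"}
DEVICES = {"watch", "phone", "unknown"}


@dataclass
class Dialect:
    """Shape of one delimited-text sensor log.

    ``timestamp_format`` is ``"epoch_ms"`` (integer milliseconds since the
    Unix epoch, UTC) or ``"iso8601"``.
    """

    delimiter: str = ","
    timestamp_format: str = "epoch_ms"
    columns: dict[str, str] = field(default_factory=dict)  # canonical -> file column

    def col(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


def _parse_timestamps(raw: pd.Series, dialect: Dialect, path) -> pd.Series:
    try:
        if dialect.timestamp_format == "epoch_ms":
            ts = pd.to_datetime(pd.to_numeric(raw, errors="raise"), unit="ms", utc=True)
        elif dialect.timestamp_format == "iso8601":
            ts = pd.to_datetime(raw, utc=True, format="ISO8601")
        else:
            raise ValueError(f"unknown timestamp_format {dialect.timestamp_format!r}")
        if ts.isna().any():
            raise ValueError("NaT produced")
        return ts
    except (ValueError, TypeError) as exc:
        bad = raw[pd.to_datetime(raw, errors="coerce", utc=True, format="mixed").isna()] if dialect.timestamp_format == "iso8601" else raw[pd.to_numeric(raw, errors="coerce").isna()]
        row = int(bad.index[0]) if len(bad) else 0
        raise ValueError(f"{path}: unparseable timestamp at data row {row}: {exc}") from exc


def _read_raw(path, dialect: Dialect, canonical: list[str], optional: set[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str, skipinitialspace=True)
    rename = {dialect.col(c): c for c in canonical}
    missing = [dialect.col(c) for c in canonical if dialect.col(c) not in raw.columns and c not in optional]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    raw = raw.rename(columns=rename)
    return raw


def _finish(df: pd.DataFrame, keep: pd.Series, path, what: str) -> pd.DataFrame:
    n_rejected = int((~keep).sum())
    if n_rejected:
        logger.warning("%s: rejected %d malformed %s row(s) at data rows %s",
                       path, n_rejected, what, list(df.index[~keep][:10]))
    out = df[keep].sort_values("timestamp", kind="stable").reset_index(drop=True)
    out.attrs["n_rejected"] = n_rejected
    return out


def read_location_log(path, dialect: Dialect | None = None) -> pd.DataFrame:
    """Read a GPS fix log into a time-sorted DataFrame.

    Columns of the result: ``timestamp`` (tz-aware UTC), ``lat``, ``lon``,
    ``accuracy_m``, ``device``. Rows with out-of-bounds coordinates or a
    negative/non-finite accuracy are rejected and counted in
    ``.attrs["n_rejected"]``.
    """
    dialect = dialect or Dialect()
    raw = _read_raw(path, dialect, LOCATION_COLUMNS, optional={"device"})
    df = pd.DataFrame({"timestamp": _parse_timestamps(raw["timestamp"], dialect, path)})
    for c in ("lat", "lon", "accuracy_m"):
        df[c] = pd.to_numeric(raw[c], errors="coerce")
    df["device"] = raw["device"].fillna("unknown") if "device" in raw else "unknown"
    df.loc[~df["device"].isin(DEVICES), "device"] = "unknown"

    keep = (
        df["lat"].between(-90, 90)
        & df["lon"].between(-180, 180)
        & (df["accuracy_m"] >= 0)
        & np.isfinite(df["accuracy_m"].to_numpy(dtype=float, na_value=np.nan))
    )
    return _finish(df, keep.fillna(False), path, "location")


def read_activity_log(path, dialect: Dialect | None = None) -> pd.DataFrame:
    """Read an activity-recognition log (timestamp, activity, confidence).

    Multiple readings may legitimately share a timestamp; all are retained.
    Unknown labels or confidences outside [0, 100] reject the row.
    """
    dialect = dialect or Dialect()
    raw = _read_raw(path, dialect, ACTIVITY_COLUMNS, optional=set())
    df = pd.DataFrame({
        "timestamp": _parse_timestamps(raw["timestamp"], dialect, path),
        "activity": raw["activity"].str.strip(),
        "confidence": pd.to_numeric(raw["confidence"], errors="coerce"),
    })
    keep = df["activity"].isin(ACTIVITY_LABELS) & df["confidence"].between(0, 100)
    out = _finish(df, keep.fillna(False), path, "activity")
    out["confidence"] = out["confidence"].astype(int)
    return out


def read_step_log(path, dialect: Dialect | None = None) -> pd.DataFrame:
    """Read a cumulative step-counter log (timestamp, count, device).

    Counts are cumulative since device boot and may *decrease* across a
    reboot; such rows are valid input. Negative counts reject the row.
    """
    dialect = dialect or Dialect()
    raw = _read_raw(path, dialect, STEP_COLUMNS, optional={"device"})
    df = pd.DataFrame({
        "timestamp": _parse_timestamps(raw["timestamp"], dialect, path),
        "count": pd.to_numeric(raw["count"], errors="coerce"),
    })
    df["device"] = raw["device"].fillna("phone") if "device" in raw else "phone"
    keep = (df["count"] >= 0) & (df["count"] == df["count"].round())
    out = _finish(df, keep.fillna(False), path, "step")
    out["count"] = out["count"].astype(np.int64)
    return out


def filter_by_accuracy(fixes: pd.DataFrame, max_accuracy_m: float = 25.0) -> pd.DataFrame:
    """Keep fixes with horizontal accuracy <= ``max_accuracy_m`` (inclusive).

    25 m is the preprocessing ceiling used for all trajectory work. Order is
    preserved.
    """
    if max_accuracy_m < 0:
        raise ValueError("max_accuracy_m must be non-negative")
    return fixes[fixes["accuracy_m"] <= max_accuracy_m].reset_index(drop=True)


_DEVICE_PRIORITY = {"watch": 0, "phone": 1, "unknown": 2}


def merge_streams(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Merge two fix streams (e.g. watch and phone) into one timeline.

    The union is sorted by timestamp; exact duplicates (same timestamp, lat,
    lon) collapse to one row. Distinct fixes sharing a timestamp are all
    kept, ordered watch-before-phone for determinism. Commutative and
    idempotent.
    """
    merged = pd.concat([a, b], ignore_index=True)
    merged = merged.drop_duplicates(subset=["timestamp", "lat", "lon"], keep="first")
    prio = merged["device"].map(_DEVICE_PRIORITY).fillna(9)
    merged = (
        merged.assign(_prio=prio)
        .sort_values(["timestamp", "_prio", "lat", "lon"], kind="stable")
        .drop(columns="_prio")
        .reset_index(drop=True)
    )
    return merged


# ---------------------------------------------------------------------------
# output


def write_events(events: pd.DataFrame, path, subject: str = "s1") -> None:
    """Write a trajectory event table as CSV (lossless round-trip)."""
    out = events.copy()
    if "subject" not in out.columns:
        out.insert(0, "subject", subject)
    out = out[EVENT_COLUMNS]
    # default stringification keeps full (nanosecond) precision -> lossless
    out.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    """Read back a trajectory event table written by :func:`write_events`."""
    df = pd.read_csv(path)
    for c in ("start_utc", "end_utc"):
        df[c] = pd.to_datetime(df[c], utc=True, format="mixed")
    df["day"] = pd.to_datetime(df["day"]).dt.date
    df["place_id"] = df["place_id"].astype("Int64")
    df["is_home"] = df["is_home"].astype(bool)
    return df


def events_to_geojson(events: pd.DataFrame, labeled: pd.DataFrame | None = None) -> dict:
    """Render a trajectory as a GeoJSON FeatureCollection (RFC 7946).

    Stays become Point features (place_id, is_home properties); moves become
    LineString features tracing their fixes (falling back to a start/end
    two-point line when per-fix geometry is unavailable). Coordinates are
    [lon, lat].
    """
    features = []
    for _, ev in events.iterrows():
        props = {"kind": ev["kind"], "day": str(ev["day"]), "seq": int(ev["seq"])}
        if ev["kind"] == "stay":
            props["place_id"] = int(ev["place_id"]) if pd.notna(ev["place_id"]) else None
            props["is_home"] = bool(ev["is_home"])
            geom = {"type": "Point", "coordinates": [float(ev["centroid_lon"]), float(ev["centroid_lat"])]}
        else:
            coords = None
            if labeled is not None and "event_id" in labeled.columns and "event_id" in ev.index:
                pts = labeled[labeled["event_id"] == ev["event_id"]]
                if len(pts) >= 2:
                    coords = [[float(lo), float(la)] for la, lo in zip(pts["lat"], pts["lon"])]
            if coords is None:
                coords = [
                    [float(ev["centroid_lon"]), float(ev["centroid_lat"])],
                    [float(ev["centroid_lon"]), float(ev["centroid_lat"])],
                ]
            geom = {"type": "LineString", "coordinates": coords}
        features.append({"type": "Feature", "geometry": geom, "properties": props})
    return {"type": "FeatureCollection", "features": features}


def write_outputs(
    out_prefix,
    events: pd.DataFrame | None = None,
    daily: pd.DataFrame | None = None,
    bouts: pd.DataFrame | None = None,
    labeled: pd.DataFrame | None = None,
    subject: str = "s1",
) -> list[Path]:
    """Write whichever result tables are provided under ``out_prefix``.

    Produces ``<prefix>_events.csv``, ``<prefix>_daily_metrics.csv``,
    ``<prefix>_bouts.csv`` and ``<prefix>_trajectory.geojson`` as applicable;
    returns the paths written.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if events is not None:
        p = prefix.parent / f"{prefix.name}_events.csv"
        write_events(events, p, subject=subject)
        written.append(p)
        g = prefix.parent / f"{prefix.name}_trajectory.geojson"
        g.write_text(json.dumps(events_to_geojson(events, labeled), indent=1))
        written.append(g)
    if daily is not None:
        p = prefix.parent / f"{prefix.name}_daily_metrics.csv"
        d = daily.copy()
        if "subject" not in d.columns:
            d.insert(0, "subject", subject)
        d.to_csv(p, index=False)
        written.append(p)
    if bouts is not None:
        p = prefix.parent / f"{prefix.name}_bouts.csv"
        b = bouts.copy()
        if "subject" not in b.columns:
            b.insert(0, "subject", subject)
        b.to_csv(p, index=False, date_format="%Y-%m-%dT%H:%M:%S.%f%z")
        written.append(p)
    return written
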