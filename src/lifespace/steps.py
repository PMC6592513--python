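"""Daily step totals from boot-cumulative counter readings.

Phone and watch pedometers report a running count of steps since the device
last booted; a reboot resets the register, so the raw series is piecewise
increasing with occasional drops. Totals are rebuilt per day and per device:

* the first reading of a local day contributes nothing (steps before it are
  unobservable and left uncounted — totals are conservative);
* each later reading contributes ``count_i - count_{i-1}`` when
  non-negative;
* a negative difference marks a reboot; the post-reboot reading itself is
  taken as the increment, a lower bound on the steps actually walked while
  the counter was down.

Watch and phone series are never fused: inter-device step disparity is
large, so each device keeps its own daily series.
"""

from __future__ import annotations

from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

DAILY_STEP_COLUMNS = ["day", "device", "total", "n_readings", "n_gaps_gt_60min"]


def daily_steps(readings: pd.DataFrame, timezone: str = "UTC") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-day, per-device step totals and within-day cumulative series.

    Returns ``(summary, series)``: the summary has one row per (day, device)
    with the total and reading counts; the series holds the per-reading
    running within-day sum (monotone non-decreasing).
    """
    tz = ZoneInfo(timezone)
    series_rows = []
    summary_rows = []
    for device, sub in readings.groupby("device", sort=True):
        sub = sub.sort_values("timestamp").reset_index(drop=True)
        day = sub["timestamp"].dt.tz_convert(tz).dt.date
        for d, grp in sub.groupby(day, sort=True):
            counts = grp["count"].to_numpy(dtype=np.int64)
            diffs = np.diff(counts)
            incs = np.where(diffs >= 0, diffs, counts[1:])  # reboot: counter restarted near 0
            cum = np.concatenate([[0], np.cumsum(incs)])
            gaps = _gaps(grp["timestamp"], 60.0)
            for ts, c in zip(grp["timestamp"], cum):
                series_rows.append({"day": d, "device": device, "timestamp": ts, "cum_steps": int(c)})
            summary_rows.append({
                "day": d, "device": device, "total": int(cum[-1]),
                "n_readings": len(grp), "n_gaps_gt_60min": len(gaps),
            })
    summary = pd.DataFrame(summary_rows, columns=DAILY_STEP_COLUMNS)
    series = pd.DataFrame(series_rows, columns=["day", "device", "timestamp", "cum_steps"])
    return summary, series


def _gaps(timestamps: pd.Series, max_gap_minutes: float) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    ts = timestamps.sort_values().reset_index(drop=True)
    out = []
    gaps = ts.diff().dt.total_seconds() / 60.0
    for i in np.flatnonzero((gaps > max_gap_minutes).to_numpy()):
        out.append((ts.iloc[i - 1], ts.iloc[i]))
    return out


def flag_gaps(readings: pd.DataFrame, max_gap_minutes: float = 60.0, timezone: str = "UTC") -> pd.DataFrame:
    """List reading gaps longer than ``max_gap_minutes``, per device per day.

    Long silent periods are common on watches; steps are still accumulated
    across them, so daily totals survive, but within-day timing does not.
    """
    tz = ZoneInfo(timezone)
    rows = []
    for device, sub in readings.groupby("device", sort=True):
        sub = sub.sort_values("timestamp")
        day = sub["timestamp"].dt.tz_convert(tz).dt.date
        for d, grp in sub.groupby(day, sort=True):
            for start, end in _gaps(grp["timestamp"], max_gap_minutes):
                rows.append({
                    "day": d, "device": device, "gap_start": start, "gap_end": end,
                    "gap_min": (end - start).total_seconds() / 60.0,
                })
    return pd.DataFrame(rows, columns=["day", "device", "gap_start", "gap_end", "gap_min"])
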