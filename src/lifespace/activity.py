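"""Activity-bout extraction from activity-recognition readings.

Device-side activity recognition emits (timestamp, label, confidence)
readings roughly every 5 minutes, possibly several per timestamp. The bout
pipeline:

1. keep only the four labels of interest — *still*, *on_foot*, *bicycle*,
   *vehicle* — relabelling *walking*/*running* to *on_foot* and dropping
   *tilting*/*unknown*;
2. within each distinct timestamp keep only the maximum-confidence
   reading(s); confidence ties keep all tied labels;
3. per activity type, group readings whose inter-reading gap is at most
   10 minutes into one bout; discard single-reading bouts;
4. number the surviving bouts chronologically per day by start time.

Move events of a trajectory can then be annotated with the transport mode
whose bouts overlap them longest.
"""

from __future__ import annotations

from zoneinfo import ZoneInfo

import pandas as pd

ACTIVITIES_OF_INTEREST = ["still", "on_foot", "bicycle", "vehicle"]
_RELABEL = {"walking": "on_foot", "running": "on_foot", "on_bicycle": "bicycle", "in_vehicle": "vehicle"}
_DROP = {"tilting", "unknown"}

BOUT_COLUMNS = ["day", "bout_number", "activity", "start_utc", "end_utc", "duration_min", "n_readings"]


def preprocess_activities(readings: pd.DataFrame) -> pd.DataFrame:
    """Reduce raw readings to per-timestamp maximum-confidence labels.

    Walking and running fold into *on_foot* (the bout granularity of
    interest); tilting and unknown are discarded. Where several labels tie
    for the maximum confidence at one timestamp, all are kept — the instant
    is genuinely multi-label.
    """
    df = readings.copy()
    df["activity"] = df["activity"].replace(_RELABEL)
    df = df[~df["activity"].isin(_DROP)]
    df = df[df["activity"].isin(ACTIVITIES_OF_INTEREST)]
    if df.empty:
        return df.reset_index(drop=True)
    # after relabelling, identical (timestamp, activity) rows are duplicates
    df = df.sort_values(["timestamp", "confidence"], kind="stable")
    df = df.drop_duplicates(subset=["timestamp", "activity"], keep="last")
    best = df.groupby("timestamp")["confidence"].transform("max")
    df = df[df["confidence"] == best]
    return df.sort_values(["timestamp", "activity"], kind="stable").reset_index(drop=True)


def extract_bouts(
    readings: pd.DataFrame,
    gap_seconds: float = 600.0,
    timezone: str = "UTC",
) -> pd.DataFrame:
    """Group preprocessed readings into per-day numbered activity bouts.

    Within one activity type, consecutive readings separated by at most
    ``gap_seconds`` belong to the same bout. Bouts with a single reading are
    dropped. A bout's day is the local date of its start; bouts are numbered
    1..K chronologically within each day.
    """
    tz = ZoneInfo(timezone)
    rows = []
    for act, sub in readings.groupby("activity", sort=False):
        sub = sub.sort_values("timestamp")
        t = sub["timestamp"]
        new_bout = (t.diff().dt.total_seconds() > gap_seconds).fillna(True)
        bout_id = new_bout.cumsum()
        for _, grp in sub.groupby(bout_id):
            if len(grp) < 2:
                continue
            start, end = grp["timestamp"].iloc[0], grp["timestamp"].iloc[-1]
            rows.append({
                "day": start.tz_convert(tz).date(),
                "activity": act,
                "start_utc": start,
                "end_utc": end,
                "duration_min": (end - start).total_seconds() / 60.0,
                "n_readings": len(grp),
            })
    bouts = pd.DataFrame(rows, columns=[c for c in BOUT_COLUMNS if c != "bout_number"])
    if bouts.empty:
        bouts["bout_number"] = pd.Series(dtype=int)
        return bouts[BOUT_COLUMNS]
    bouts = bouts.sort_values(["start_utc", "activity"], kind="stable").reset_index(drop=True)
    bouts["bout_number"] = bouts.groupby("day", sort=False).cumcount() + 1
    return bouts[BOUT_COLUMNS]


def annotate_moves(events: pd.DataFrame, bouts: pd.DataFrame) -> pd.DataFrame:
    """Attach a dominant transport mode to every move event.

    The dominant mode is the non-still activity with the largest total bout
    overlap with the move's time span; a tie goes to the earlier-starting
    bout's mode. Moves with no overlapping transport bout are ``unknown``.
    Returns the move events with ``mode`` and ``mode_overlap_min`` columns.
    """
    moves = events[events["kind"] == "move"].copy()
    transport = bouts[bouts["activity"] != "still"]
    modes, overlaps = [], []
    for _, mv in moves.iterrows():
        per_mode: dict[str, float] = {}
        first_start: dict[str, pd.Timestamp] = {}
        for _, b in transport.iterrows():
            lo = max(mv["start_utc"], b["start_utc"])
            hi = min(mv["end_utc"], b["end_utc"])
            ov = (hi - lo).total_seconds() / 60.0
            if ov > 0:
                per_mode[b["activity"]] = per_mode.get(b["activity"], 0.0) + ov
                if b["activity"] not in first_start or b["start_utc"] < first_start[b["activity"]]:
                    first_start[b["activity"]] = b["start_utc"]
        if per_mode:
            best = max(per_mode.items(), key=lambda kv: (kv[1], -first_start[kv[0]].value))
            modes.append(best[0])
            overlaps.append(best[1])
        else:
            modes.append("unknown")
            overlaps.append(0.0)
    moves["mode"] = modes
    moves["mode_overlap_min"] = overlaps
    return moves
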