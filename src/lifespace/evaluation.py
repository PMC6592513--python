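"""Evaluation against reference logs.

Three statistics quantify agreement between the sensor pipeline and a
reference record (participant log sheets, or the simulator's ground truth):

* **move-detection sensitivity** — each reference move is matched one-to-one
  to the nearest unmatched detected move whose start time differs by at
  most a window (default 30 min, reflecting the imprecision of hand-kept
  logs); sensitivity = matched / total reference moves;
* **daily-metric residuals** — per paired day, residual = algorithm −
  reference; summarised as RMSD, mean and sample SD;
* **transport confusion** — an occurrence matrix of reference vs detected
  move modes restricted to a label subset (canonically bicycle/vehicle,
  the recurring confusion of device activity recognition), with accuracy =
  diagonal fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ResidualSummary:
    """RMSD / mean / SD of per-day algorithm-minus-reference residuals."""

    metric: str
    residuals: np.ndarray
    rmsd: float
    mean: float
    sd: float
    n_days: int
    n_excluded: int


@dataclass
class ConfusionMatrix:
    """Occurrence counts of reference (rows) vs detected (columns) labels."""

    labels: tuple[str, ...]
    counts: np.ndarray
    accuracy: float


def match_moves(
    detected: pd.DataFrame,
    reference: pd.DataFrame,
    window_min: float = 30.0,
) -> tuple[pd.DataFrame, float]:
    """Greedy one-to-one matching of reference moves to detected moves.

    Candidate pairs within ``window_min`` of each other (start-time
    difference) are taken closest-first; each detected move can absorb only
    one reference move. Returns ``(matches, sensitivity)``; sensitivity is
    NaN when there are no reference moves. Matching is done within subject
    when both tables carry a ``subject`` column.
    """
    det = detected[detected["kind"] == "move"].reset_index(drop=True)
    ref = reference[reference["kind"] == "move"].reset_index(drop=True)
    if len(ref) == 0:
        return pd.DataFrame(columns=["ref_idx", "det_idx", "delta_min"]), float("nan")

    by_subject = "subject" in det.columns and "subject" in ref.columns
    pairs = []
    for i, r in ref.iterrows():
        for j, d in det.iterrows():
            if by_subject and r["subject"] != d["subject"]:
                continue
            delta = abs((d["start_utc"] - r["start_utc"]).total_seconds()) / 60.0
            if delta <= window_min:
                pairs.append((delta, i, j))
    pairs.sort()
    used_ref: set = set()
    used_det: set = set()
    rows = []
    for delta, i, j in pairs:
        if i in used_ref or j in used_det:
            continue
        used_ref.add(i)
        used_det.add(j)
        rows.append({"ref_idx": i, "det_idx": j, "delta_min": delta})
    matches = pd.DataFrame(rows, columns=["ref_idx", "det_idx", "delta_min"])
    return matches, len(matches) / len(ref)


def metric_residuals(
    algo_daily: pd.DataFrame,
    ref_daily: pd.DataFrame,
    metric: str,
) -> ResidualSummary:
    """Summarise daily algorithm − reference residuals for one metric.

    Days present on only one side (or with a missing value) are excluded
    and counted. Raises when no paired days remain.
    """
    keys = [k for k in ("subject", "day") if k in algo_daily.columns and k in ref_daily.columns]
    merged = algo_daily.merge(ref_daily, on=keys, suffixes=("_algo", "_ref"), how="outer")
    a = merged.get(f"{metric}_algo", merged.get(metric))
    r = merged.get(f"{metric}_ref")
    if r is None:
        raise KeyError(f"metric {metric!r} absent from reference table")
    resid = (a - r).astype(float)
    ok = resid.notna()
    n_excluded = int((~ok).sum())
    resid = resid[ok].to_numpy()
    if resid.size == 0:
        raise ValueError("no paired days to compare")
    rmsd = float(np.sqrt(np.mean(resid ** 2)))
    mean = float(np.mean(resid))
    sd = float(np.std(resid, ddof=1)) if resid.size > 1 else 0.0
    return ResidualSummary(metric=metric, residuals=resid, rmsd=rmsd, mean=mean,
                           sd=sd, n_days=int(resid.size), n_excluded=n_excluded)


def transport_confusion(
    pairs: pd.DataFrame,
    labels: tuple[str, ...] = ("bicycle", "vehicle"),
    ref_col: str = "ref_mode",
    det_col: str = "det_mode",
) -> ConfusionMatrix:
    """Reference-vs-detected mode occurrence matrix on a label subset.

    Only moves whose reference *and* detected labels both fall inside
    ``labels`` enter the matrix. Raises when the subset is empty.
    """
    sel = pairs[pairs[ref_col].isin(labels) & pairs[det_col].isin(labels)]
    if sel.empty:
        raise ValueError("no moves with both labels in the requested subset")
    idx = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for _, row in sel.iterrows():
        counts[idx[row[ref_col]], idx[row[det_col]]] += 1
    return ConfusionMatrix(labels=tuple(labels), counts=counts,
                           accuracy=float(np.trace(counts) / counts.sum()))


def evaluate_dataset(
    dataset: list[dict],
    seg_cfg=None,
    timezone: str = "UTC",
    window_min: float = 30.0,
) -> dict:
    """Run the full pipeline on a simulated dataset and score it.

    ``dataset`` is the output of :func:`lifespace.synthetic.simulate_dataset`.
    For every subject the trajectory is extracted from the rendered GPS
    stream and compared against the jittered log sheet (sensitivity and
    daily residuals); activity bouts are extracted from the rendered
    readings and used to annotate the true moves for the transport
    confusion matrix.
    """
    from .activity import annotate_moves, extract_bouts, preprocess_activities
    from .metrics import daily_metrics
    from .trajectory import SegmentationConfig, extract_trajectories

    seg_cfg = seg_cfg or SegmentationConfig()
    det_moves, ref_moves, algo_daily, mode_pairs = [], [], [], []
    for entry in dataset:
        sch = entry["schedule"]
        res = extract_trajectories(entry["gps"], seg_cfg, timezone)
        ev = res.events.copy()
        ev["subject"] = sch.subject
        det_moves.append(ev)
        ref = entry["logsheet"].copy()
        ref["subject"] = sch.subject
        ref_moves.append(ref)
        d = daily_metrics(res, timezone)
        d.insert(0, "subject", sch.subject)
        algo_daily.append(d)

        bouts = extract_bouts(preprocess_activities(entry["activity"]), timezone=timezone)
        ann = annotate_moves(sch.events, bouts)
        true_moves = sch.events[sch.events["kind"] == "move"]
        mode_pairs.append(pd.DataFrame({
            "subject": sch.subject,
            "ref_mode": true_moves["mode"].to_numpy(),
            "det_mode": ann["mode"].to_numpy(),
        }))

    det = pd.concat(det_moves, ignore_index=True)
    ref = pd.concat(ref_moves, ignore_index=True)
    algo = pd.concat(algo_daily, ignore_index=True)
    refd = logsheet_daily(ref)
    pairs = pd.concat(mode_pairs, ignore_index=True)

    matches, sensitivity = match_moves(det, ref, window_min)
    residuals = {
        m: metric_residuals(algo, refd, m) for m in ("n_places", "time_out_min")
    }
    try:
        confusion = transport_confusion(pairs)
    except ValueError:
        confusion = None
    return {
        "sensitivity": sensitivity,
        "n_ref_moves": int((ref["kind"] == "move").sum()),
        "matches": matches,
        "residuals": residuals,
        "confusion": confusion,
        "mode_pairs": pairs,
        "algo_daily": algo,
        "ref_daily": refd,
    }


def logsheet_daily(logsheet: pd.DataFrame) -> pd.DataFrame:
    """Daily reference metrics derivable from a log sheet.

    Unique places, time out of home, trip count and time moving — the
    measures a diarist's record supports.
    """
    rows = []
    keys = ["subject", "day"] if "subject" in logsheet.columns else ["day"]
    for key, grp in logsheet.groupby(keys, sort=True):
        stays = grp[grp["kind"] == "stay"]
        moves = grp[grp["kind"] == "move"]
        away = grp[~((grp["kind"] == "stay") & grp["is_home"].astype(bool))]
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update({
            "n_places": int(stays["place_id"].dropna().nunique()),
            "time_out_min": float(away["duration_min"].sum()),
            "n_trips": int(len(moves)),
            "time_moving_min": float(moves["duration_min"].sum()),
        })
        rows.append(row)
    return pd.DataFrame(rows)
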