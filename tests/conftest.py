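import numpy as np
import pandas as pd
import pytest

T0 = pd.Timestamp("2024-03-04", tz="UTC")

HOME = (55.70, 12.50)
# ~3 km due east of HOME at this latitude
WORK = (55.70, 12.50 + 3000.0 / (111_194.93 * np.cos(np.radians(55.70))))


def fixes_frame(minutes, lats, lons, accuracy=5.0, device="phone"):
    """Build a location-fix DataFrame at T0 + the given minute offsets."""
    n = len(minutes)
    return pd.DataFrame({
        "timestamp": [T0 + pd.Timedelta(minutes=float(m)) for m in minutes],
        "lat": np.broadcast_to(np.asarray(lats, dtype=float), (n,)).copy(),
        "lon": np.broadcast_to(np.asarray(lons, dtype=float), (n,)).copy(),
        "accuracy_m": np.broadcast_to(np.asarray(accuracy, dtype=float), (n,)).copy(),
        "device": device,
    })


def labeled_frame(runs):
    """Build a labelled-fix DataFrame from (state, place_id, minutes, lat, lon) runs."""
    parts = []
    for state, place, minutes, lat, lon in runs:
        df = fixes_frame(minutes, lat, lon)
        df["state"] = state
        df["place_id"] = place
        df["is_home"] = False
        parts.append(df)
    out = pd.concat(parts, ignore_index=True).sort_values("timestamp").reset_index(drop=True)
    out["place_id"] = out["place_id"].astype("Int64")
    return out


@pytest.fixture(scope="session")
def commute_day():
    """Noise-free home -> work -> home day sampled every 200 s.

    Returns (fixes, truth) where truth records the designed transition
    minutes: home stay 00:00-09:00, 30-min move, work 09:30-15:00, 30-min
    move, home 15:30-24:00. Fixes are 4 min apart.
    """
    step = 4.0  # minutes between fixes; within the 5-min look-ahead window
    minutes, lats, lons = [], [], []

    def span(m0, m1, pos_fn):
        m = m0
        while m < m1:
            la, lo = pos_fn(m)
            minutes.append(m)
            lats.append(la)
            lons.append(lo)
            m += step

    at_home = lambda m: HOME
    at_work = lambda m: WORK

    def travelling(m0, m1, a, b):
        def f(m):
            frac = (m - m0) / (m1 - m0)
            return a[0] + frac * (b[0] - a[0]), a[1] + frac * (b[1] - a[1])
        return f

    span(0, 9 * 60, at_home)
    span(9 * 60, 9 * 60 + 30, travelling(9 * 60, 9 * 60 + 30, HOME, WORK))
    span(9 * 60 + 30, 15 * 60, at_work)
    span(15 * 60, 15 * 60 + 30, travelling(15 * 60, 15 * 60 + 30, WORK, HOME))
    span(15 * 60 + 30, 24 * 60, at_home)

    truth = {
        "transitions_min": [9 * 60, 9 * 60 + 30, 15 * 60, 15 * 60 + 30],
        "n_stays": 3,
        "n_moves": 2,
        "work_distance_km": 3.0,
    }
    return fixes_frame(minutes, lats, lons), truth
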