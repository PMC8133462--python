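"""From raw tower records to homes, hourly positions and distances.

The measurement chain: (i) towers give coordinates; (ii) a phone's home is
the dwell-weighted average of the towers it used during the night window
(0:00-6:00, pooled over all days of the raw period); (iii) its position in an
hour is the dwell-weighted average of that hour's towers; (iv) the distance
from home is binned into 501 intervals of 100 m, censored at 50 km, and
represented by the interval midpoint.

Hour t denotes the interval (t-1:00, t:00], handled as the half-open window
[(t-1)*3600, t*3600) so no second is double-counted across hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SECONDS_PER_HOUR = 3600
SECONDS_PER_DAY = 86400

#: distance bin layout: edges [0,100], (100,200], ..., (49900,50000], (50000,inf)
BIN_WIDTH = 100.0
CENSOR_LIMIT = 50_000.0


@dataclass
class SelectionRules:
    """Raw-data sample-selection thresholds.

    A phone is kept when its raw record count and its first-to-last time span
    both meet the thresholds; the defaults (20 records, 96 hours) drop
    temporary visitors.
    """

    min_records: int = 20
    min_span_hours: float = 96.0


def filter_users(records: pd.DataFrame,
                 rules: SelectionRules | None = None) -> pd.Index:
    """Phone ids passing the record-count and active-span rules."""
    rules = SelectionRules() if rules is None else rules
    if records.empty:
        return pd.Index([], name="phone_id")
    g = records.groupby("phone_id")["timestamp"]
    stats = pd.DataFrame({"n": g.size(), "span": g.max() - g.min()})
    keep = stats[(stats["n"] >= rules.min_records)
                 & (stats["span"] >= rules.min_span_hours * SECONDS_PER_HOUR)]
    return keep.index


def _intervals(records: pd.DataFrame) -> pd.DataFrame:
    """Per-phone connection intervals [start, end) with their tower.

    Each inter-event gap is attributed to the tower of the opening event;
    a disconnect opens a gap attributed to no tower; a service event renews
    the connection to its tower. The final interval of each phone is
    unterminated and is clipped later by the caller's window.
    """
    df = records.sort_values(["phone_id", "timestamp"], kind="stable")
    start = df["timestamp"].to_numpy(dtype=float)
    end = np.empty_like(start)
    end[:-1] = start[1:]
    end[-1] = np.inf
    # last record of each phone has no successor
    phone = df["phone_id"].to_numpy()
    last = np.ones(len(df), dtype=bool)
    last[:-1] = phone[:-1] != phone[1:]
    end[last] = np.inf
    out = pd.DataFrame({
        "phone_id": phone, "tower_id": df["tower_id"].to_numpy(),
        "start": start, "end": end,
        "open": df["event"].to_numpy() != "disconnect"})
    return out[out["open"]].drop(columns="open").reset_index(drop=True)


def dwell_times(records: pd.DataFrame, window: tuple[float, float],
                towers: pd.DataFrame | None = None) -> pd.Series:
    """Seconds connected to each tower within the half-open window.

    Reconnections to the same tower merge naturally because dwell is summed
    over intervals. Raises if a record references a tower missing from the
    tower table (when one is supplied).
    """
    if towers is not None:
        unknown = set(records["tower_id"]) - set(towers["tower_id"])
        if unknown:
            raise KeyError(f"records reference unknown towers: {sorted(unknown)[:5]}")
    w0, w1 = window
    iv = _intervals(records)
    lo = np.maximum(iv["start"].to_numpy(), w0)
    hi = np.minimum(iv["end"].to_numpy(), w1)
    dur = np.maximum(hi - lo, 0.0)
    out = pd.Series(dur, index=iv["tower_id"]).groupby(level=0).sum()
    return out[out > 0]


def hourly_dwell(records: pd.DataFrame, towers: pd.DataFrame,
                 *, end_time: float | None = None) -> pd.DataFrame:
    """Dwell seconds per (phone, absolute hour, tower) over the whole stream.

    Vectorized equivalent of calling :func:`dwell_times` for every phone-hour
    window. ``end_time`` clips the unterminated final interval of each phone
    (default: the last timestamp in the stream).
    """
    unknown = set(records["tower_id"]) - set(towers["tower_id"])
    if unknown:
        raise KeyError(f"records reference unknown towers: {sorted(unknown)[:5]}")
    iv = _intervals(records)
    if end_time is None:
        end_time = float(records["timestamp"].max())
    end = np.minimum(iv["end"].to_numpy(), end_time)
    start = iv["start"].to_numpy()
    valid = end > start
    iv, start, end = iv[valid], start[valid], end[valid]

    first_h = np.floor(start / SECONDS_PER_HOUR).astype(int)
    last_h = np.ceil(end / SECONDS_PER_HOUR).astype(int) - 1
    last_h = np.maximum(last_h, first_h)
    n_pieces = last_h - first_h + 1
    rep = np.repeat(np.arange(len(iv)), n_pieces)
    piece = np.concatenate([np.arange(k) for k in n_pieces]) if len(iv) else \
        np.array([], dtype=int)
    hour_abs = first_h[rep] + piece
    lo = np.maximum(start[rep], hour_abs * SECONDS_PER_HOUR)
    hi = np.minimum(end[rep], (hour_abs + 1) * SECONDS_PER_HOUR)
    dur = hi - lo
    keep = dur > 0
    out = pd.DataFrame({
        "phone_id": iv["phone_id"].to_numpy()[rep][keep],
        "hour_abs": hour_abs[keep],
        "tower_id": iv["tower_id"].to_numpy()[rep][keep],
        "seconds": dur[keep]})
    return (out.groupby(["phone_id", "hour_abs", "tower_id"], as_index=False)
            ["seconds"].sum())


def weighted_position(dwell: pd.Series, towers: pd.DataFrame) -> tuple[float, float]:
    """Dwell-weighted average of tower coordinates.

    Returns None-signalling ``(nan, nan)`` is *not* produced here: zero total
    dwell raises, and callers treat missing phone-hours as "no fix".
    """
    total = float(dwell.sum())
    if total <= 0:
        raise ValueError("zero total dwell: no position fix")
    tw = towers.set_index("tower_id").loc[dwell.index]
    w = dwell.to_numpy() / total
    return float(w @ tw["x"].to_numpy()), float(w @ tw["y"].to_numpy())


def infer_homes(dwell: pd.DataFrame, towers: pd.DataFrame,
                night_window: tuple[int, int] = (0, 6)) -> pd.DataFrame:
    """Home estimates: pooled night dwell-weighted tower average per phone.

    ``dwell`` is the output of :func:`hourly_dwell`. Night hours are those
    whose window lies within [night_window) o'clock on any day. Phones with
    no night dwell are absent from the result (the "no-home" signal); the
    caller logs and excludes them downstream.
    """
    h0, h1 = night_window
    hod = dwell["hour_abs"] % 24
    night = dwell[(hod >= h0) & (hod < h1)]
    if night.empty:
        return pd.DataFrame(columns=["phone_id", "x", "y", "n_night_towers",
                                     "total_night_seconds"])
    agg = night.groupby(["phone_id", "tower_id"])["seconds"].sum().reset_index()
    tw = towers.set_index("tower_id")
    agg["wx"] = agg["seconds"] * tw["x"].reindex(agg["tower_id"]).to_numpy()
    agg["wy"] = agg["seconds"] * tw["y"].reindex(agg["tower_id"]).to_numpy()
    g = agg.groupby("phone_id")
    out = pd.DataFrame({
        "total_night_seconds": g["seconds"].sum(),
        "n_night_towers": g["tower_id"].nunique(),
        "x": g["wx"].sum() / g["seconds"].sum(),
        "y": g["wy"].sum() / g["seconds"].sum()}).reset_index()
    return out[["phone_id", "x", "y", "n_night_towers", "total_night_seconds"]]


def bin_distance(d):
    """Bin distance into 100 m intervals, censored at 50 km.

    Edges are [0,100], (100,200], ...: a distance exactly on a 100k boundary
    belongs to the lower interval. Returns (midpoint, censored_upper); beyond
    the censor limit the midpoint is pinned at 50,000 m.
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative distance (upstream bug)")
    k = np.ceil(arr / BIN_WIDTH).astype(int)
    k = np.maximum(k, 1)                      # d = 0 belongs to [0, 100]
    mid = k * BIN_WIDTH - BIN_WIDTH / 2
    censored = arr > CENSOR_LIMIT
    mid = np.where(censored, CENSOR_LIMIT, mid)
    if arr.ndim == 0:
        return float(mid), bool(censored)
    return mid, censored


def hourly_placements(dwell: pd.DataFrame, towers: pd.DataFrame,
                      homes: pd.DataFrame, *, hours: list[int],
                      days: list[int] | None = None) -> pd.DataFrame:
    """Per phone-hour positions, cities and binned distances from home.

    Restricted to the analysed ``hours`` of day. City assignment follows the
    tower with maximal dwell (ties broken by lexicographic city id). Phones
    without a home estimate are dropped. Columns: phone_id, city, day, hour,
    x, y, distance, distance_mid, censored_upper, dwell_seconds.
    """
    tw = towers.set_index("tower_id")
    d = dwell.copy()
    d["day"] = d["hour_abs"] // 24
    # hour t denotes the interval (t-1, t], i.e. the window [t-1:00, t:00)
    d["hour"] = d["hour_abs"] % 24 + 1
    d = d[d["hour"].isin(hours)]
    if days is not None:
        d = d[d["day"].isin(days)]
    d["tx"] = tw["x"].reindex(d["tower_id"]).to_numpy()
    d["ty"] = tw["y"].reindex(d["tower_id"]).to_numpy()
    d["tcity"] = tw["city"].reindex(d["tower_id"]).to_numpy()
    d["wx"] = d["seconds"] * d["tx"]
    d["wy"] = d["seconds"] * d["ty"]

    g = d.groupby(["phone_id", "day", "hour"])
    pos = pd.DataFrame({
        "dwell_seconds": g["seconds"].sum(),
        "x": g["wx"].sum() / g["seconds"].sum(),
        "y": g["wy"].sum() / g["seconds"].sum()})
    # city of max dwell, ties to lexicographically smallest city id
    bycity = (d.groupby(["phone_id", "day", "hour", "tcity"])["seconds"].sum()
              .reset_index()
              .sort_values(["phone_id", "day", "hour", "seconds", "tcity"],
                           ascending=[True, True, True, False, True]))
    city = bycity.drop_duplicates(["phone_id", "day", "hour"]).set_index(
        ["phone_id", "day", "hour"])["tcity"]
    pos["city"] = city
    pos = pos.reset_index()

    hm = homes.set_index("phone_id")
    pos = pos[pos["phone_id"].isin(hm.index)]
    hx = hm["x"].reindex(pos["phone_id"]).to_numpy()
    hy = hm["y"].reindex(pos["phone_id"]).to_numpy()
    pos["distance"] = np.hypot(pos["x"] - hx, pos["y"] - hy)
    pos["distance_mid"], pos["censored_upper"] = bin_distance(
        pos["distance"].to_numpy())
    return pos[["phone_id", "city", "day", "hour", "x", "y", "distance",
                "distance_mid", "censored_upper", "dwell_seconds"]].reset_index(
        drop=True)


def geolocate(records: pd.DataFrame, towers: pd.DataFrame, *,
              rules: SelectionRules | None = None,
              night_window: tuple[int, int] = (0, 6),
              hours: list[int] | None = None,
              days: list[int] | None = None) -> dict:
    """Full measurement stage: filter, infer homes, place phone-hours.

    Returns a dict with ``placements``, ``homes``, ``dwell`` and a ``log`` of
    drop counts (filtered phones, no-home phones).
    """
    hours = list(range(7, 23)) if hours is None else hours
    eligible = filter_users(records, rules)
    kept = records[records["phone_id"].isin(eligible)]
    n_dropped = records["phone_id"].nunique() - len(eligible)
    dwell = hourly_dwell(kept, towers)
    homes = infer_homes(dwell, towers, night_window)
    n_nohome = len(eligible) - len(homes)
    placements = hourly_placements(dwell, towers, homes, hours=hours, days=days)
    return {"placements": placements, "homes": homes, "dwell": dwell,
            "log": {"phones_total": int(records["phone_id"].nunique()),
                    "phones_filtered_out": int(n_dropped),
                    "phones_no_home": int(n_nohome)}}
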