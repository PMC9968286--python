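"""Public transport service frequency (headway) analysis.

For every stop, the average daytime (07:00-19:00, closed window) weekday
headway over an analysis window is the mean over served days of the daily
mean gap between consecutive departures; days with fewer than two daytime
departures do not contribute.  A stop is "regular" when this average is
30 minutes or less (inclusive), considered jointly across all modes.  The
address-level indicator scores the distance to the closest regular stop
(taken from the 800 m stop distance array) against a 400 m threshold.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import access as access_mod
from .access import DistanceArray

#: Daytime window, minutes since midnight (closed interval).
DAY_START_MIN = 7 * 60
DAY_END_MIN = 19 * 60
#: "Regular" service threshold (minutes, inclusive).
REGULAR_HEADWAY_MIN = 30.0
#: Access threshold for the regular-transport indicator (metres).
PT_THRESHOLD_M = 400.0


@dataclass
class StopHeadway:
    stop_id: object
    mode: str
    mean_headway_min: float | None
    n_days: int
    regular: bool


def _parse_minutes(value) -> float:
    """Departure time to minutes since midnight; accepts 'HH:MM:SS' or a
    numeric minutes value."""
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    h, m, *rest = str(value).split(":")
    s = float(rest[0]) if rest else 0.0
    return int(h) * 60 + int(m) + s / 60.0


def stop_headways(
    stop_times: pd.DataFrame,
    window: tuple[dt.date, dt.date] | None = None,
    weekdays_only: bool = True,
    time_window: tuple[float, float] = (DAY_START_MIN, DAY_END_MIN),
    min_days: int = 1,
    modes: dict | None = None,
) -> dict:
    """Average daytime weekday headway per stop.

    ``stop_times`` needs columns ``stop_id, service_date, departure_time``.
    Per stop and qualifying day, the headway is the mean gap between
    consecutive daytime departures (both endpoints inside the closed time
    window); the stop's mean headway averages the daily means over days with
    at least two such departures (and at least ``min_days`` served days).
    Modes are treated jointly; ``modes`` only labels the output.
    """
    if stop_times.empty:
        return {}
    df = stop_times.copy()
    dates = pd.to_datetime(df["service_date"]).dt.date
    if window is not None:
        start, end = window
        keep = (dates >= start) & (dates <= end)
        df, dates = df[keep], dates[keep]
    if weekdays_only:
        keep = pd.to_datetime(pd.Series(list(dates))).dt.weekday < 5
        df, dates = df[np.asarray(keep)], dates[np.asarray(keep)]
    minutes = df["departure_time"].map(_parse_minutes)
    lo, hi = time_window
    keep = (minutes >= lo) & (minutes <= hi)
    df = pd.DataFrame(
        {"stop_id": df["stop_id"][keep], "date": dates[keep], "minute": minutes[keep]}
    )

    out: dict = {}
    for stop_id, grp in df.groupby("stop_id", sort=True):
        daily = []
        for _, day in grp.groupby("date"):
            times = np.sort(day["minute"].to_numpy(float))
            if len(times) >= 2:
                daily.append(float(np.diff(times).mean()))
        mode = (modes or {}).get(stop_id, "")
        if len(daily) >= max(min_days, 1):
            mean = float(np.mean(daily))
            out[stop_id] = StopHeadway(stop_id, mode, mean, len(daily),
                                       regular=mean <= REGULAR_HEADWAY_MIN)
        else:
            out[stop_id] = StopHeadway(stop_id, mode, None, len(daily), regular=False)
    return out


def pt_regular_access(
    stop_array: DistanceArray,
    headways: dict,
    threshold_m: float = PT_THRESHOLD_M,
    mode: str = "soft",
    k: float = access_mod.DEFAULT_SOFT_K,
) -> float:
    """Score access to regular public transport: the distance to the closest
    stop classified regular (within the stop array's 800 m cutoff), scored
    at 400 m."""
    if stop_array.pooled:
        raise ValueError("stop arrays must be single-source")
    if stop_array.ids is None:
        raise ValueError("stop array must carry stop ids")
    d = None
    for dist, stop_id in zip(stop_array.distances, stop_array.ids):
        hw = headways.get(stop_id)
        if hw is not None and hw.regular:
            d = dist
            break
    return access_mod.score(d, threshold_m, mode=mode, k=k)


def headway_table(headways: dict, stops: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-stop headway summary as a DataFrame (with WKT geometry when a
    stops table is supplied)."""
    rows = [
        {
            "stop_id": hw.stop_id,
            "mode": hw.mode,
            "mean_headway_min": hw.mean_headway_min,
            "n_days": hw.n_days,
            "regular": hw.regular,
        }
        for hw in headways.values()
    ]
    df = pd.DataFrame(rows).sort_values("stop_id").reset_index(drop=True)
    if stops is not None:
        import shapely

        geom = stops.set_index("stop_id")["geometry"]
        df["wkt"] = [
            shapely.to_wkt(geom[s], rounding_precision=-1) if s in geom.index else ""
            for s in df["stop_id"]
        ]
        mode = stops.set_index("stop_id")["mode"]
        df["mode"] = [mode.get(s, "") for s in df["stop_id"]]
    return df
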