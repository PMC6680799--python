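"""Circadian activity metrics: diurnality index, activity onset relative to
civil dusk, and daily ODBA sums.

The per-minute activity proxy is the accumulated SD (aSD) of each burst.  Two
deliberately different day windows are used, each anchored to its own
definition: the diurnality index and activity onset use the dawn-to-dawn day
(civil dawn opens the day), while behaviour budgets and daily ODBA sums use
the civil calendar day (00:00-23:59) together with the >= 1430-burst
completeness filter.

Diurnality index
    DI = (A_d/T_d - A_n/T_n) / (A_d/T_d + A_n/T_n), where A_d, A_n are the
    summed aSD in daylight (dawn..dusk) and night (dusk..next dawn) and
    T_d, T_n the corresponding durations.  The rate normalization makes DI
    insensitive to the unequal lengths of day and night; DI = -1 is fully
    nocturnal, +1 fully diurnal.

Activity onset / TSdusk
    Minutes are "active" when aSD exceeds a threshold, by default the mean
    aSD over the individual's full deployment.  Onset is the first run of k
    consecutive active minutes in the dawn-to-dawn day (k = 1 by default);
    TSdusk = onset - civil dusk in signed minutes (negative before dusk).
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class TwilightTable:
    """Lookup of civil dawn/dusk instants per date."""

    def __init__(self, table: pd.DataFrame):
        t = table.copy()
        t["date"] = pd.to_datetime(t["date"]).dt.date
        t["civil_dawn"] = pd.to_datetime(t["civil_dawn"])
        t["civil_dusk"] = pd.to_datetime(t["civil_dusk"])
        self._dawn = dict(zip(t["date"], t["civil_dawn"]))
        self._dusk = dict(zip(t["date"], t["civil_dusk"]))

    def dawn(self, date: dt.date) -> pd.Timestamp:
        return self._dawn[date]

    def dusk(self, date: dt.date) -> pd.Timestamp:
        return self._dusk[date]

    def covers(self, date: dt.date) -> bool:
        return date in self._dawn


def minute_series(features: pd.DataFrame) -> pd.DataFrame:
    """Per-minute aSD series (one burst per minute) from a feature table."""
    out = features[["individual_id", "timestamp", "asd"]].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.floor("min")
    return out.sort_values(["individual_id", "timestamp"]).reset_index(drop=True)


def asd_threshold(series: pd.DataFrame, by: str = "individual") -> dict[str, float]:
    """Active/passive aSD threshold: the mean aSD over the deployment.

    ``by='individual'`` (default) averages per individual over its full
    deployment; ``by='global'`` uses one pooled mean for everyone.
    """
    if by == "global":
        g = float(series["asd"].mean())
        return {i: g for i in series["individual_id"].unique()}
    if by == "individual":
        return series.groupby("individual_id")["asd"].mean().to_dict()
    raise ValueError(f"unknown threshold scope: {by!r}")


def diurnality_index(
    day_series: pd.DataFrame,
    dawn: pd.Timestamp,
    dusk: pd.Timestamp,
    next_dawn: pd.Timestamp,
) -> float:
    """DI for one dawn-to-dawn day; NaN (day skipped) if total activity is 0."""
    ts = day_series["timestamp"]
    day_mask = (ts >= dawn) & (ts < dusk)
    night_mask = (ts >= dusk) & (ts < next_dawn)
    if not day_mask.any() or not night_mask.any():
        raise ValueError("day and night segments must both be non-empty")
    a_d = float(day_series.loc[day_mask, "asd"].sum())
    a_n = float(day_series.loc[night_mask, "asd"].sum())
    t_d = (dusk - dawn).total_seconds()
    t_n = (next_dawn - dusk).total_seconds()
    if a_d + a_n == 0.0:
        logger.warning("zero total activity between %s and %s; DI undefined", dawn, next_dawn)
        return float("nan")
    r_d = a_d / t_d
    r_n = a_n / t_n
    return (r_d - r_n) / (r_d + r_n)


def activity_onset(
    day_series: pd.DataFrame, threshold: float, k: int = 1
) -> pd.Timestamp | None:
    """First run of >= k consecutive minutes with aSD > threshold, or None."""
    if k < 1:
        raise ValueError("run length k must be >= 1")
    s = day_series.sort_values("timestamp")
    active = (s["asd"] > threshold).to_numpy()
    ts = s["timestamp"].to_numpy()
    run = 0
    for i, a in enumerate(active):
        run = run + 1 if a else 0
        if run >= k:
            return pd.Timestamp(ts[i - k + 1])
    return None


def tsdusk(onset: pd.Timestamp, civil_dusk: pd.Timestamp) -> float:
    """Signed minutes from civil dusk to activity onset (positive = after)."""
    return (pd.Timestamp(onset) - pd.Timestamp(civil_dusk)).total_seconds() / 60.0


def daily_odba(features: pd.DataFrame, min_bursts: int = 1430) -> pd.DataFrame:
    """Per individual-day ODBA sums over the civil calendar day.

    Days with fewer than ``min_bursts`` kept bursts between 00:00 and 23:59
    are excluded (completeness filter).
    """
    df = features.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.date
    agg = (
        df.groupby(["individual_id", "date"])
        .agg(daily_odba=("odba", "sum"), n_bursts=("odba", "size"))
        .reset_index()
    )
    return agg[agg["n_bursts"] >= min_bursts].reset_index(drop=True)


def rhythm_table(
    features: pd.DataFrame,
    twilight: pd.DataFrame | TwilightTable,
    k: int = 1,
    min_bursts: int = 1430,
    threshold_by: str = "individual",
) -> pd.DataFrame:
    """Per individual-day DI, onset, TSdusk and daily ODBA.

    The row's ``date`` is the dawn date of the dawn-to-dawn day for DI/TSdusk;
    ``daily_odba``/``n_bursts`` refer to the same calendar date's 00:00-23:59
    window (NaN where that day fails the completeness filter).
    """
    tw = twilight if isinstance(twilight, TwilightTable) else TwilightTable(twilight)
    series = minute_series(features)
    thresholds = asd_threshold(series, by=threshold_by)
    odba_tab = daily_odba(features, min_bursts=min_bursts)
    odba_map = {
        (r.individual_id, r.date): (r.daily_odba, r.n_bursts)
        for r in odba_tab.itertuples()
    }
    rows = []
    for ind, s in series.groupby("individual_id"):
        dates = sorted(s["timestamp"].dt.date.unique())
        for d in dates:
            nxt = d + dt.timedelta(days=1)
            if not (tw.covers(d) and tw.covers(nxt)):
                continue
            dawn, dusk_t, next_dawn = tw.dawn(d), tw.dusk(d), tw.dawn(nxt)
            day_s = s[(s["timestamp"] >= dawn) & (s["timestamp"] < next_dawn)]
            if day_s.empty:
                continue
            ts = day_s["timestamp"]
            if not ((ts < dusk_t).any() and (ts >= dusk_t).any()):
                continue  # need both day and night coverage
            if ts.max() < next_dawn - pd.Timedelta(minutes=2):
                continue  # truncated night (deployment end) would bias DI
            di = diurnality_index(day_s, dawn, dusk_t, next_dawn)
            onset = activity_onset(day_s, thresholds[ind], k=k)
            ts_d = tsdusk(onset, dusk_t) if onset is not None else float("nan")
            od, nb = odba_map.get((ind, d), (float("nan"), 0))
            rows.append(
                {
                    "individual_id": ind,
                    "date": d,
                    "DI": di,
                    "onset": onset,
                    "TSdusk_min": ts_d,
                    "daily_odba": od,
                    "n_bursts": nb,
                    "no_onset": onset is None,
                }
            )
    return pd.DataFrame(rows)
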