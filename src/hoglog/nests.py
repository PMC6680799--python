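"""Nest-utilization spells, Kaplan-Meier curves and the log-rank test.

Daily nest checks (one record per individual per day) are converted into
*spells*: maximal runs of consecutive days in the same nest.  A spell ends
with an event (event = 1) when the next day's check finds a different nest.
Spells running into a phase boundary, a gap in the checks, or the end of
monitoring are censored there (event = 0); a new spell opens on the other
side.  Phase-boundary censoring keeps each spell inside one phase so phases
can be compared on the same animals.

The survival function of spell duration is the Kaplan-Meier product-limit
estimate (via lifelines), and phases are compared per sex with the standard
log-rank (Mantel) statistic with tie correction, reported as a signed Z
(observed minus expected events in group A) and a two-sided normal p-value.
The "non-festival" group pools the pre-festival days and the post-festival
monitoring days.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .config import PhaseCalendar


def build_spells(
    checks: pd.DataFrame, calendar: PhaseCalendar | None = None
) -> pd.DataFrame:
    """Run-length encode daily nest checks into censored utilization spells.

    ``checks`` needs individual_id, sex, date, nest_id.  Conflicting
    duplicate checks (same individual and date, different nest) raise with
    the offending dates listed; identical duplicates are dropped.
    """
    if calendar is None:
        calendar = PhaseCalendar()
    df = checks.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df = df.drop_duplicates(["individual_id", "date", "nest_id"])
    dup = df.duplicated(["individual_id", "date"], keep=False)
    if dup.any():
        bad = df.loc[dup, ["individual_id", "date"]].drop_duplicates()
        raise ValueError(
            "conflicting duplicate nest checks for: "
            + ", ".join(f"{r.individual_id}@{r.date}" for r in bad.itertuples())
        )
    df = df.sort_values(["individual_id", "date"])

    rows = []
    for ind, g in df.groupby("individual_id", sort=False):
        sex = g["sex"].iloc[0]
        recs = list(g.itertuples())
        start = recs[0]
        dur = 1
        gap_censored = False
        for prev, cur in zip(recs, recs[1:]):
            contiguous = (cur.date - prev.date) == dt.timedelta(days=1)
            same_phase = calendar.phase_of(cur.date) == calendar.phase_of(prev.date)
            if contiguous and same_phase and cur.nest_id == prev.nest_id:
                dur += 1
                continue
            event = int(contiguous and same_phase and cur.nest_id != prev.nest_id)
            rows.append(
                _spell_row(start, sex, dur, event, calendar, gap_censored=not contiguous)
            )
            start = cur
            dur = 1
        rows.append(_spell_row(start, sex, dur, 0, calendar, gap_censored=False))
    return pd.DataFrame(rows)


def _spell_row(start, sex, dur, event, calendar, gap_censored):
    phase = calendar.phase_of(start.date)
    return {
        "individual_id": start.individual_id,
        "sex": sex,
        "nest_id": start.nest_id,
        "start": start.date,
        "duration_days": dur,
        "event": event,
        "phase": phase,
        "phase_group": "festival" if phase == "festival" else "nonfestival",
        "gap_censored": bool(gap_censored),
    }


def km_curve(durations, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival estimate.

    Returns a step table (time, survival, n_risk, n_events); S(0) = 1 and the
    function is non-increasing and right-continuous.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    if durations.size == 0:
        raise ValueError("km_curve needs at least one spell")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    surv = kmf.survival_function_["KM_estimate"]
    tab = kmf.event_table
    out = pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.to_numpy(dtype=float),
            "n_risk": tab["at_risk"].reindex(surv.index).to_numpy(dtype=float),
            "n_events": tab["observed"].reindex(surv.index).to_numpy(dtype=float),
        }
    )
    return out.reset_index(drop=True)


def logrank(
    durations_a, events_a, durations_b, events_b
) -> tuple[float, float]:
    """Signed log-rank (Mantel) statistic with tie correction.

    Z is signed as (observed - expected) events in group A; p is two-sided
    from the normal approximation.  Raises if no events occur at all.
    """
    da = np.asarray(durations_a, dtype=float)
    db = np.asarray(durations_b, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    if da.size == 0 or db.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank undefined: no events in either group")
    times = np.unique(np.concatenate([da[ea == 1], db[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        n1 = float((da >= t).sum())
        n2 = float((db >= t).sum())
        d1 = float(((da == t) & (ea == 1)).sum())
        d2 = float(((db == t) & (eb == 1)).sum())
        n = n1 + n2
        d = d1 + d2
        if n < 1 or d == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var <= 0.0:
        return 0.0, 1.0
    z = o_minus_e / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def nest_survival_summary(spells: pd.DataFrame) -> pd.DataFrame:
    """Per-sex comparison of festival vs pooled non-festival spell durations.

    Reports the signed log-rank Z and p plus both candidate denominators the
    raw counts admit: number of spells and number of nest-days.
    """
    rows = []
    for sex, g in spells.groupby("sex"):
        fest = g[g["phase_group"] == "festival"]
        non = g[g["phase_group"] == "nonfestival"]
        if len(fest) == 0 or len(non) == 0:
            continue
        try:
            z, p = logrank(
                fest["duration_days"], fest["event"],
                non["duration_days"], non["event"],
            )
        except ValueError:
            z, p = float("nan"), float("nan")
        rows.append(
            {
                "sex": sex,
                "z": z,
                "p": p,
                "n_spells": len(g),
                "n_nest_days": int(g["duration_days"].sum()),
                "n_spells_festival": len(fest),
                "n_spells_nonfestival": len(non),
                "median_duration_festival": float(fest["duration_days"].median()),
                "median_duration_nonfestival": float(non["duration_days"].median()),
            }
        )
    return pd.DataFrame(rows)
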