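"""Per-day glycaemia summaries, event classification and recurrence risk.

A stay-day ``d`` is the 24 h block ``[intime + (d-1)*24h, intime + d*24h)``
anchored at ICU admission, so the first day is never a partial calendar
day.  The daily average is time-weighted under last-observation-carried-
forward: each reading covers the interval up to the next reading (or the
day/stay end), and the first reading of the day also covers the stretch
back to the day start.  Bursts of rapid repeat measurements therefore do
not distort the average.

Recurrence is quantified as a discrete-time relative risk: among stays
observed on consecutive days, the probability of an event on day ``d+1``
given an event on day ``d``, divided by the same probability given no
event — pooled over day pairs 1..6 Mantel-Haenszel style.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Thresholds

logger = logging.getLogger(__name__)

__all__ = ["time_weighted_mean", "daily_summaries", "table2_shares",
           "day1_day7_cohort", "recurrence_hazard", "HazardRatioResult"]


def time_weighted_mean(times, values, start, end) -> float:
    """LOCF time-weighted mean of readings over the interval [start, end).

    ``times`` must be sorted and lie within the interval.  Each reading
    is weighted by the time from its charttime to the next reading (the
    last one extends to ``end``); the first reading additionally covers
    from ``start`` back to its charttime.  Weights therefore sum to the
    interval length.  Raises ``ValueError`` on an empty interval or zero
    readings.
    """
    times = pd.DatetimeIndex(times)
    values = np.asarray(values, dtype=float)
    if len(times) == 0:
        raise ValueError("time_weighted_mean needs at least one reading")
    if end <= start:
        raise ValueError("empty interval")
    edges = times.append(pd.DatetimeIndex([end]))
    weights = np.asarray((edges[1:] - edges[:-1]).total_seconds(), dtype=float)
    weights[0] += (times[0] - start).total_seconds()
    total = weights.sum()
    return float(np.dot(weights, values) / total)


def daily_summaries(glucose: pd.DataFrame, stays: pd.DataFrame,
                    thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """One row per stay-day with at least one glucose measurement.

    Columns: ``tw_mean``, ``min``, ``max``, ``n_measurements``, the
    non-exclusive event flags ``hypo_event`` (any reading < hypo) and
    ``hyper_event`` (any reading > hyper, strict inequalities), and an
    exclusive display ``class`` with priority hypo > hyper > eu (a day
    with both kinds of excursion is shown as hypo, the rarer and more
    dangerous event).
    """
    stay_info = stays.set_index("icustay_id")[["intime", "outtime"]]
    rows = []
    for sid, grp in glucose.groupby("icustay_id"):
        if sid not in stay_info.index:
            continue
        intime = stay_info.at[sid, "intime"]
        outtime = stay_info.at[sid, "outtime"]
        grp = grp.sort_values(["charttime", "row_id"], kind="stable")
        day_idx = ((grp["charttime"] - intime).dt.total_seconds() // 86400
                   ).astype(int) + 1
        for d, day_grp in grp.groupby(day_idx):
            day_start = intime + pd.Timedelta(hours=24 * (d - 1))
            day_end = min(intime + pd.Timedelta(hours=24 * d), outtime)
            if day_end <= day_start:  # reading charted exactly at outtime
                day_end = intime + pd.Timedelta(hours=24 * d)
            vals = day_grp["valuenum"].to_numpy(dtype=float)
            tw = time_weighted_mean(day_grp["charttime"], vals,
                                    day_start, day_end)
            hypo = bool((vals < thresholds.hypo).any())
            hyper = bool((vals > thresholds.hyper).any())
            rows.append(dict(
                icustay_id=sid, day_index=int(d), tw_mean=tw,
                min=float(vals.min()), max=float(vals.max()),
                n_measurements=len(vals), hypo_event=hypo, hyper_event=hyper,
                day_class="hypo" if hypo else ("hyper" if hyper else "eu"),
            ))
    return pd.DataFrame(rows, columns=[
        "icustay_id", "day_index", "tw_mean", "min", "max",
        "n_measurements", "hypo_event", "hyper_event", "day_class"])


_INDICATORS = {
    "avg_below_hypo": lambda df, t: df["tw_mean"] < t.hypo,
    "avg_above_hyper": lambda df, t: df["tw_mean"] > t.hyper,
    "min_below_hypo": lambda df, t: df["min"] < t.hypo,
    "max_above_hyper": lambda df, t: df["max"] > t.hyper,
    "min_below_severe_hypo": lambda df, t: df["min"] < t.severe_hypo,
    "max_above_severe_hyper": lambda df, t: df["max"] > t.severe_hyper,
}


def table2_shares(daily: pd.DataFrame, stays: pd.DataFrame,
                  days: tuple[int, ...] = (1, 7),
                  thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Shares of stays with abnormal daily glycaemia, by day and stratum.

    For each requested day and diabetic stratum, the proportion of stays
    (among those with any measurement that day — day-specific
    denominators) whose time-weighted average, minimum or maximum
    crosses each classification threshold.
    """
    flag = stays.set_index("icustay_id")["diabetic"]
    out = []
    for day in days:
        sub = daily[daily["day_index"] == day].copy()
        sub["diabetic"] = sub["icustay_id"].map(flag).astype(bool)
        for stratum, grp in (("non_diabetic", sub[~sub["diabetic"]]),
                             ("diabetic", sub[sub["diabetic"]])):
            row = {"day": day, "stratum": stratum, "n": len(grp)}
            for name, fn in _INDICATORS.items():
                row[name] = float(fn(grp, thresholds).mean()) if len(grp) else np.nan
            out.append(row)
    return pd.DataFrame(out)


def day1_day7_cohort(daily: pd.DataFrame, stays: pd.DataFrame) -> pd.DataFrame:
    """Each subject's first ICU stay with readings on both day 1 and day 7."""
    present = daily.groupby("icustay_id")["day_index"].apply(set)
    qualifying = {sid for sid, ds in present.items() if 1 in ds and 7 in ds}
    sub = stays[stays["icustay_id"].isin(qualifying)]
    first = (sub.sort_values(["intime", "icustay_id"], kind="stable")
             .groupby("subject_id", as_index=False).first())
    return first.reset_index(drop=True)


@dataclass
class HazardRatioResult:
    """Next-day recurrence relative risks for one event type.

    ``per_day`` holds the 2x2 day-pair counts (n11: event day d and
    d+1, n10: event d only, n01: event d+1 only among no-event-d, n00:
    neither) with each day's relative risk; ``pooled`` aggregates counts
    over day pairs before forming the ratio and is the headline number;
    ``mean_rr`` is the unweighted mean of per-day ratios.
    """

    event_type: str
    per_day: pd.DataFrame
    pooled: float | None
    mean_rr: float | None


def recurrence_hazard(daily: pd.DataFrame, event_type: str,
                      max_day: int = 7) -> HazardRatioResult:
    """Relative risk of an event recurring the next day, days 1..max_day.

    A stay contributes the day pair (d, d+1) only when it has at least
    one measurement on both days.  RR_d = P(event d+1 | event d) /
    P(event d+1 | no event d); the pooled ratio uses summed counts.
    Days with an undefined ratio are excluded from pooling with a
    warning.
    """
    col = {"hypo": "hypo_event", "hyper": "hyper_event"}[event_type]
    flags = daily.pivot_table(index="icustay_id", columns="day_index",
                              values=col, aggfunc="first")
    rows = []
    for d in range(1, max_day):
        if d not in flags.columns or (d + 1) not in flags.columns:
            rows.append(dict(day=d, n11=0, n10=0, n01=0, n00=0, rr=np.nan))
            continue
        sub = flags[[d, d + 1]].dropna()
        a = sub[d].astype(bool)
        b = sub[d + 1].astype(bool)
        n11 = int((a & b).sum())
        n10 = int((a & ~b).sum())
        n01 = int((~a & b).sum())
        n00 = int((~a & ~b).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            p1 = n11 / (n11 + n10) if (n11 + n10) else np.nan
            p0 = n01 / (n01 + n00) if (n01 + n00) else np.nan
            rr = p1 / p0 if (p0 and not np.isnan(p1)) else np.nan
        rows.append(dict(day=d, n11=n11, n10=n10, n01=n01, n00=n00, rr=rr))
    per_day = pd.DataFrame(rows)

    s = per_day[["n11", "n10", "n01", "n00"]].sum()
    exposed = s["n11"] + s["n10"]
    unexposed = s["n01"] + s["n00"]
    pooled = None
    if exposed and unexposed and s["n01"] > 0:
        pooled = float((s["n11"] / exposed) / (s["n01"] / unexposed))
    elif exposed == 0 or unexposed == 0 or s["n01"] == 0:
        warnings.warn(f"recurrence_hazard({event_type}): pooled ratio "
                      "undefined (degenerate counts)", stacklevel=2)
    valid = per_day["rr"].dropna()
    if valid.isna().any() or len(valid) < len(per_day):
        logger.warning("recurrence_hazard(%s): %d of %d day pairs had an "
                       "undefined ratio", event_type,
                       len(per_day) - len(valid), len(per_day))
    mean_rr = float(valid.mean()) if len(valid) else None
    return HazardRatioResult(event_type=event_type, per_day=per_day,
                             pooled=pooled, mean_rr=mean_rr)
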