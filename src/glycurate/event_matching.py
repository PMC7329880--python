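"""Temporal pairing of short-acting insulin boluses with glucose readings.

EMR event tables do not link a charted insulin dose to the measurement
that prompted it.  Clinically, a short-acting bolus follows a recent
glucose reading, but bedside charting rounds bolus timestamps (often to
the hour) and occasionally records the two events in the wrong order.
The pairing rule therefore searches a window of ``before`` minutes back
and ``after`` minutes forward of each bolus charttime (defaults 60/10,
both boundaries inclusive) and links the bolus to the **most recent**
candidate measurement.  Boluses with no candidate are discarded as
unmatched.  Only short-acting boluses are matched; infusions and
intermediate/long-acting insulin are never paired.

Before matching, boluses confounded by non-glycaemic insulin indications
are removed: all insulin from stays with a primary diagnosis of diabetic
ketoacidosis, beta-blocker overdose or hyperkalaemia, and any bolus
within one hour (two-sided) of a calcium-gluconate input in the same
stay — the insulin/calcium combination treats hyperkalaemia, not blood
sugar.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ConfigError, MatchWindow

__all__ = ["exclude_confounded", "match", "match_rate"]

PAIR_COLUMNS = ["bolus_row_id", "glucose_row_id", "icustay_id", "bolus_time",
                "glucose_time", "lag_minutes", "glucose_mgdl", "dose_units"]


def exclude_confounded(insulin: pd.DataFrame, stays: pd.DataFrame,
                       calcium_events: pd.DataFrame,
                       exclusion_minutes: float = 60.0
                       ) -> tuple[pd.DataFrame, dict]:
    """Drop insulin events confounded by non-glycaemic indications.

    Removes every insulin event from stays flagged ``excluded_dx`` and
    every short-acting bolus whose charttime lies within
    ``exclusion_minutes`` (inclusive, two-sided) of any calcium-gluconate
    event in the same stay.  Returns the retained events and per-rule
    drop counts.
    """
    df = insulin.copy()
    counts = {"excluded_dx": 0, "calcium_gluconate": 0}

    if "excluded_dx" in stays.columns:
        bad_stays = set(stays.loc[stays["excluded_dx"].astype(bool), "icustay_id"])
        drop = df["icustay_id"].isin(bad_stays)
        counts["excluded_dx"] = int(drop.sum())
        df = df[~drop]

    if len(calcium_events):
        tol = pd.Timedelta(minutes=exclusion_minutes)
        cal_by_stay = {
            sid: np.sort(g["charttime"].to_numpy())
            for sid, g in calcium_events.groupby("icustay_id")
        }

        def near_calcium(row) -> bool:
            if row["insulin_kind"] != "short_bolus":
                return False
            times = cal_by_stay.get(row["icustay_id"])
            if times is None:
                return False
            t = np.datetime64(row["charttime"])
            i = np.searchsorted(times, t)
            for j in (i - 1, i):
                if 0 <= j < len(times) and abs(pd.Timestamp(times[j]) - row["charttime"]) <= tol:
                    return True
            return False

        drop = df.apply(near_calcium, axis=1) if len(df) else pd.Series(dtype=bool)
        counts["calcium_gluconate"] = int(drop.sum())
        df = df[~drop] if len(df) else df

    return df.reset_index(drop=True), counts


def match(insulin: pd.DataFrame, glucose: pd.DataFrame,
          window: MatchWindow = MatchWindow(),
          tie_break: tuple[str, ...] = ("value", "row_id"),
          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair each short-acting bolus with its most recent glucose reading.

    Candidates are measurements in the same stay with charttime in
    ``[bolus - before, bolus + after]`` (inclusive).  The latest
    candidate wins; exact-timestamp ties break by highest glucose value
    then lowest record id (configurable via ``tie_break``).  One
    measurement may match several boluses (split doses charted
    separately), so matching is independent of bolus order.

    Returns ``(pairs, unmatched_boluses)``; the lag is signed as
    measurement time minus bolus time, so charting-order inversions give
    positive lags up to ``after``.
    """
    if not isinstance(window, MatchWindow):
        raise ConfigError("match() requires a MatchWindow")
    boluses = insulin[insulin["insulin_kind"] == "short_bolus"]
    before = np.timedelta64(int(round(window.before * 60)), "s")
    after = np.timedelta64(int(round(window.after * 60)), "s")

    pair_rows = []
    unmatched_idx = []
    gluc_groups = {sid: g for sid, g in glucose.groupby("icustay_id")}
    for sid, bgroup in boluses.groupby("icustay_id"):
        g = gluc_groups.get(sid)
        if g is None or not len(g):
            unmatched_idx.extend(bgroup.index)
            continue
        g = g.sort_values(["charttime", "row_id"], kind="stable")
        times = g["charttime"].to_numpy()
        values = g["valuenum"].to_numpy()
        rowids = g["row_id"].to_numpy()
        for idx, bolus in bgroup.iterrows():
            t = np.datetime64(bolus["charttime"])
            lo = np.searchsorted(times, t - before, side="left")
            hi = np.searchsorted(times, t + after, side="right")
            if lo >= hi:
                unmatched_idx.append(idx)
                continue
            latest = times[hi - 1]
            lo_tie = np.searchsorted(times, latest, side="left")
            cand = np.arange(lo_tie, hi)
            for key in tie_break:
                if len(cand) == 1:
                    break
                if key == "value":
                    cand = cand[values[cand] == values[cand].max()]
                elif key == "row_id":
                    cand = cand[rowids[cand] == rowids[cand].min()]
                else:
                    raise ConfigError(f"unknown tie-break key {key!r}")
            j = int(cand[0])
            lag = (pd.Timestamp(times[j]) - bolus["charttime"]).total_seconds() / 60.0
            pair_rows.append(dict(
                bolus_row_id=bolus["row_id"], glucose_row_id=rowids[j],
                icustay_id=sid, bolus_time=bolus["charttime"],
                glucose_time=pd.Timestamp(times[j]), lag_minutes=lag,
                glucose_mgdl=values[j], dose_units=bolus["amount"],
            ))

    pairs = pd.DataFrame(pair_rows, columns=PAIR_COLUMNS)
    unmatched = boluses.loc[unmatched_idx].reset_index(drop=True)
    return pairs, unmatched


def annotate_diabetic(pairs: pd.DataFrame, stays: pd.DataFrame) -> pd.DataFrame:
    """Attach the per-stay diabetic flag to matched pairs."""
    flag = stays.set_index("icustay_id")["diabetic"]
    out = pairs.copy()
    out["diabetic"] = out["icustay_id"].map(flag).astype(bool)
    return out


def _nearest_gap_minutes(boluses: pd.DataFrame, glucose: pd.DataFrame) -> pd.Series:
    gaps = []
    gluc_groups = {sid: np.sort(g["charttime"].to_numpy())
                   for sid, g in glucose.groupby("icustay_id")}
    for _, b in boluses.iterrows():
        times = gluc_groups.get(b["icustay_id"])
        if times is None or not len(times):
            gaps.append(np.nan)
            continue
        t = np.datetime64(b["charttime"])
        i = np.searchsorted(times, t)
        best = min(
            abs((pd.Timestamp(times[j]) - b["charttime"]).total_seconds())
            for j in (i - 1, i) if 0 <= j < len(times)
        )
        gaps.append(best / 60.0)
    return pd.Series(gaps, index=boluses.index)


def match_rate(pairs: pd.DataFrame, boluses_retained: pd.DataFrame,
               glucose: pd.DataFrame | None = None,
               stays: pd.DataFrame | None = None) -> dict:
    """Proportion of retained boluses that found a match, plus diagnostics.

    When ``glucose``/``stays`` are supplied, also compares matched and
    unmatched boluses on dose, diabetic share, distance to the nearest
    measurement and time into the stay — the standard check that
    unmatched events are not a systematically different population.
    With zero retained boluses the rate is ``None``.
    """
    boluses = boluses_retained[
        boluses_retained["insulin_kind"] == "short_bolus"]
    n = len(boluses)
    result: dict = {"n_boluses": n, "n_matched": len(pairs),
                    "rate": (len(pairs) / n) if n else None}
    if n == 0:
        return result

    matched_mask = boluses["row_id"].isin(pairs["bolus_row_id"])
    groups = {"matched": boluses[matched_mask],
              "unmatched": boluses[~matched_mask]}
    comparison: dict = {}
    for label, grp in groups.items():
        entry = {"n": len(grp),
                 "mean_dose": float(grp["amount"].mean()) if len(grp) else None}
        if stays is not None and "diabetic" in stays.columns and len(grp):
            flag = stays.set_index("icustay_id")["diabetic"]
            entry["diabetic_share"] = float(
                grp["icustay_id"].map(flag).astype(bool).mean())
        if stays is not None and len(grp):
            intime = stays.set_index("icustay_id")["intime"]
            hours = (grp["charttime"] - grp["icustay_id"].map(intime)
                     ).dt.total_seconds() / 3600.0
            entry["mean_hours_into_stay"] = float(hours.mean())
        if glucose is not None and len(grp):
            entry["mean_nearest_glucose_minutes"] = float(
                _nearest_gap_minutes(grp, glucose).mean())
        comparison[label] = entry
    result["comparison"] = comparison
    return result
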