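"""Independent brute-force oracles used to cross-check the pipeline."""

import numpy as np
import pandas as pd


def brute_force_match(boluses: pd.DataFrame, glucose: pd.DataFrame,
                      before: float = 60.0, after: float = 10.0
                      ) -> pd.DataFrame:
    """All-pairs O(n*m) scan implementing the pairing rule directly.

    For every short-acting bolus, enumerate every measurement in the
    same stay, keep those with signed lag (measurement - bolus) in
    [-before, +after] minutes, and select the latest; ties break by
    highest value then lowest row id.  Deliberately naive - no sorting
    or searching shortcuts - so it is an independent check of the
    production matcher.
    """
    rows = []
    boluses = boluses[boluses["insulin_kind"] == "short_bolus"]
    for _, b in boluses.iterrows():
        g = glucose[glucose["icustay_id"] == b["icustay_id"]]
        lag = (g["charttime"] - b["charttime"]).dt.total_seconds() / 60.0
        g = g[(lag >= -before) & (lag <= after)]
        if not len(g):
            continue
        # lexicographic max over (charttime, value, -row_id)
        order = np.lexsort((-g["row_id"].to_numpy(),
                            g["valuenum"].to_numpy(),
                            g["charttime"].to_numpy().astype("datetime64[s]")))
        best = g.iloc[order[-1]]
        rows.append(dict(
            bolus_row_id=b["row_id"], glucose_row_id=best["row_id"],
            lag_minutes=(best["charttime"] - b["charttime"]
                         ).total_seconds() / 60.0))
    return pd.DataFrame(rows, columns=["bolus_row_id", "glucose_row_id",
                                       "lag_minutes"])


def random_match_instance(rng, n_stays=5, n_glucose=400, n_boluses=100):
    """A random matching instance with clustered timestamps and ties."""
    base = pd.Timestamp("2130-06-01")
    g_stay = rng.integers(1, n_stays + 1, n_glucose)
    b_stay = rng.integers(1, n_stays + 1, n_boluses)
    # minute-resolution offsets in a 3-day window force frequent ties
    g_min = rng.integers(0, 3 * 24 * 60, n_glucose)
    b_min = rng.integers(0, 3 * 24 * 60, n_boluses)
    glucose = pd.DataFrame({
        "row_id": np.arange(1, n_glucose + 1),
        "icustay_id": g_stay,
        "charttime": base + pd.to_timedelta(g_min, unit="m"),
        "valuenum": rng.integers(40, 400, n_glucose).astype(float),
    })
    boluses = pd.DataFrame({
        "row_id": np.arange(1, n_boluses + 1),
        "icustay_id": b_stay,
        "charttime": base + pd.to_timedelta(b_min, unit="m"),
        "amount": rng.integers(1, 12, n_boluses).astype(float),
        "insulin_kind": "short_bolus",
    })
    return boluses, glucose


def markov_daily_events(rng, n_stays: int, n_days: int,
                        p11: float, p01: float) -> pd.DataFrame:
    """Daily event indicators from a two-state Markov chain per stay.

    Day-1 state is drawn from the chain's stationary distribution.  The
    output mimics a daily-summaries frame (every stay present every
    day) with the hypo flag carrying the chain state.
    """
    pi1 = p01 / (1.0 - p11 + p01)
    states = np.zeros((n_stays, n_days), dtype=bool)
    states[:, 0] = rng.random(n_stays) < pi1
    for d in range(1, n_days):
        p = np.where(states[:, d - 1], p11, p01)
        states[:, d] = rng.random(n_stays) < p
    stay_ids = np.repeat(np.arange(1, n_stays + 1), n_days)
    days = np.tile(np.arange(1, n_days + 1), n_stays)
    flags = states.reshape(-1)
    return pd.DataFrame({
        "icustay_id": stay_ids, "day_index": days,
        "tw_mean": 150.0, "min": 100.0, "max": 200.0, "n_measurements": 6,
        "hypo_event": flags, "hyper_event": False,
        "day_class": np.where(flags, "hypo", "eu"),
    })


def pooled_rr_se(per_day: pd.DataFrame) -> float:
    """Delta-method standard error of the pooled relative risk.

    Uses the standard log-RR variance for pooled 2x2 counts:
    var(log RR) = (1-p1)/(n1*p1) + (1-p0)/(n0*p0).
    """
    s = per_day[["n11", "n10", "n01", "n00"]].sum()
    n1 = s["n11"] + s["n10"]
    n0 = s["n01"] + s["n00"]
    p1 = s["n11"] / n1
    p0 = s["n01"] / n0
    var_log = (1 - p1) / (n1 * p1) + (1 - p0) / (n0 * p0)
    rr = p1 / p0
    return float(rr * np.sqrt(var_log))
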