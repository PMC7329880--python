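"""Dose-given-glucose characterization of insulin use.

Covers the descriptive battery around short-acting insulin dosing: the
conditional dose distribution (heat map), an OLS regression of dose on
glucose with a diabetic-status indicator and interaction under
heteroskedasticity-robust standard errors, the probability that a
glucose measurement is followed by a bolus (spline-smoothed by stratum),
daily insulin usage by preparation kind, and the mean glucose trajectory
around initiation of an insulin infusion.

The regression is descriptive, not causal: repeated observations from
the same stay are correlated, so robust (sandwich) standard errors
understate within-patient dependence.  Coefficient estimates remain
unbiased under such clustering, which is why conclusions are drawn from
predicted doses rather than from the standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import make_smoothing_spline

from .config import ConfigError, MatchWindow

__all__ = ["DoseRegressionResult", "fit_dose_regression", "dose_heatmap",
           "DoseHeatmap", "bolus_probability", "daily_usage",
           "infusion_response"]

CLUSTERING_CAVEAT = (
    "Standard errors are heteroskedasticity-robust but multiple "
    "observations come from the same patient and are correlated; "
    "interpret inference with caution."
)

_DESIGN_COLUMNS = ("const", "glucose", "diabetic", "glucose_x_diabetic")


@dataclass
class DoseRegressionResult:
    """OLS fit of bolus dose on glucose, diabetic status and interaction.

    ``params`` are (intercept b0 in units, glucose slope b1 in units per
    mg/dL, diabetic shift b2 in units, interaction b3 in units per
    mg/dL).  ``predict`` is affine in glucose within each stratum:
    ``b0 + b1*g + diabetic*(b2 + b3*g)``.
    """

    params: dict
    robust_se: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    cov_type: str = "HC1"
    n_obs: int = 0
    caveat: str = CLUSTERING_CAVEAT

    def predict(self, glucose: float, diabetic: bool | int) -> float:
        b = self.params
        d = 1.0 if diabetic else 0.0
        return float(b["const"] + b["glucose"] * glucose
                     + d * (b["diabetic"] + b["glucose_x_diabetic"] * glucose))

    def prediction_table(self, glucose_points=(200.0, 400.0)) -> pd.DataFrame:
        """Predicted doses (2 dp) at reference glucose levels by stratum."""
        rows = [dict(glucose_mgdl=g, stratum=s,
                     predicted_dose_units=round(self.predict(g, d), 2))
                for g in glucose_points
                for s, d in (("non_diabetic", 0), ("diabetic", 1))]
        return pd.DataFrame(rows)

    @classmethod
    def from_coefficients(cls, b0: float, b1: float, b2: float, b3: float
                          ) -> "DoseRegressionResult":
        """Build a result directly from published coefficients."""
        return cls(params=dict(zip(_DESIGN_COLUMNS, (b0, b1, b2, b3))))


def fit_dose_regression(pairs: pd.DataFrame, cov_type: str = "HC1"
                        ) -> DoseRegressionResult:
    """Regress dose on {1, glucose, diabetic, glucose*diabetic}.

    Requires >= 10 pairs spanning at least two glucose values and both
    diabetic strata.  ``cov_type`` selects the sandwich flavour (HC0-HC3).
    A collinear design raises ``ConfigError`` naming the deficient
    column.
    """
    if cov_type not in {"HC0", "HC1", "HC2", "HC3"}:
        raise ConfigError(f"unsupported robust covariance type {cov_type!r}")
    if len(pairs) < 10:
        raise ConfigError("degenerate design: need at least 10 matched pairs")
    g = pairs["glucose_mgdl"].astype(float)
    d = pairs["diabetic"].astype(float)
    if g.nunique() < 2:
        raise ConfigError("degenerate design: column 'glucose' is constant")
    if d.nunique() < 2:
        raise ConfigError("degenerate design: column 'diabetic' has one stratum")

    X = pd.DataFrame({"const": 1.0, "glucose": g, "diabetic": d,
                      "glucose_x_diabetic": g * d})
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        for col in ("glucose_x_diabetic", "diabetic", "glucose"):
            reduced = X.drop(columns=[col])
            if np.linalg.matrix_rank(reduced.to_numpy()) == rank:
                raise ConfigError(f"collinear design: column {col!r} is "
                                  "linearly dependent on the others")
        raise ConfigError("collinear design")

    fit = sm.OLS(pairs["dose_units"].astype(float), X).fit(cov_type=cov_type)
    return DoseRegressionResult(
        params=fit.params.to_dict(),
        robust_se=fit.bse.to_dict(),
        p_values=fit.pvalues.to_dict(),
        cov_type=cov_type,
        n_obs=int(fit.nobs),
    )


@dataclass
class DoseHeatmap:
    """Column-normalized P(dose bin | glucose bin) over matched pairs."""

    probabilities: pd.DataFrame  # index: dose-bin labels, columns: glucose bins
    glucose_edges: np.ndarray
    dose_edges: np.ndarray
    column_counts: pd.Series


def dose_heatmap(pairs: pd.DataFrame, glucose_bin_width: float = 25.0,
                 dose_bin_width: float = 2.0) -> DoseHeatmap:
    """Conditional dose histogram: each nonempty glucose column sums to 1."""
    if not len(pairs):
        raise ConfigError("dose_heatmap requires at least one matched pair")
    g = pairs["glucose_mgdl"].astype(float).to_numpy()
    dose = pairs["dose_units"].astype(float).to_numpy()
    g_lo = np.floor(g.min() / glucose_bin_width)
    g_hi = np.floor(g.max() / glucose_bin_width) + 1
    g_edges = np.arange(g_lo, g_hi + 1) * glucose_bin_width
    d_hi = np.floor(dose.max() / dose_bin_width) + 1
    d_edges = np.arange(0, d_hi + 1) * dose_bin_width
    counts, _, _ = np.histogram2d(dose, g, bins=[d_edges, g_edges])
    col_tot = counts.sum(axis=0)
    with np.errstate(invalid="ignore"):
        probs = np.where(col_tot > 0, counts / np.where(col_tot, col_tot, 1),
                         np.nan)
    g_labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(g_edges[:-1], g_edges[1:])]
    d_labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(d_edges[:-1], d_edges[1:])]
    return DoseHeatmap(
        probabilities=pd.DataFrame(probs, index=d_labels, columns=g_labels),
        glucose_edges=g_edges, dose_edges=d_edges,
        column_counts=pd.Series(col_tot.astype(int), index=g_labels),
    )


def bolus_probability(glucose: pd.DataFrame, insulin: pd.DataFrame,
                      stays: pd.DataFrame,
                      window: MatchWindow = MatchWindow(),
                      bin_width: float = 25.0,
                      smoothing_lam: float | None = None) -> pd.DataFrame:
    """Proportion of glucose measurements followed by a short-acting bolus.

    Anchors the matching window on the measurement (reversed relative to
    bolus matching): a measurement counts as dosed iff at least one
    short-acting bolus in the same stay is charted within
    ``[measurement - after, measurement + before]``.  Returns per-bin
    proportions for all stays and the diabetic / non-diabetic strata,
    plus a cubic smoothing-spline value per stratum at the bin midpoint.
    """
    boluses = insulin[insulin["insulin_kind"] == "short_bolus"]
    back = np.timedelta64(int(round(window.after * 60)), "s")
    fwd = np.timedelta64(int(round(window.before * 60)), "s")
    bolus_times = {sid: np.sort(grp["charttime"].to_numpy())
                   for sid, grp in boluses.groupby("icustay_id")}

    dosed = np.zeros(len(glucose), dtype=bool)
    for sid, grp in glucose.groupby("icustay_id"):
        times = bolus_times.get(sid)
        if times is None:
            continue
        t = grp["charttime"].to_numpy()
        lo = np.searchsorted(times, t - back, side="left")
        hi = np.searchsorted(times, t + fwd, side="right")
        dosed[glucose.index.get_indexer(grp.index)] = hi > lo

    flag = stays.set_index("icustay_id")["diabetic"]
    df = pd.DataFrame({
        "glucose": glucose["valuenum"].astype(float).to_numpy(),
        "dosed": dosed,
        "diabetic": glucose["icustay_id"].map(flag).astype(bool).to_numpy(),
    })
    edges = np.arange(np.floor(df["glucose"].min() / bin_width) * bin_width,
                      df["glucose"].max() + bin_width, bin_width)
    df["bin_mid"] = edges[np.clip(np.digitize(df["glucose"], edges) - 1,
                                  0, len(edges) - 2)] + bin_width / 2.0

    out_rows = []
    for mid, grp in df.groupby("bin_mid"):
        row = {"bin_mid": mid, "n_all": len(grp),
               "p_all": float(grp["dosed"].mean())}
        for label, sub in (("diabetic", grp[grp["diabetic"]]),
                           ("non_diabetic", grp[~grp["diabetic"]])):
            row[f"n_{label}"] = len(sub)
            row[f"p_{label}"] = float(sub["dosed"].mean()) if len(sub) else np.nan
        out_rows.append(row)
    out = pd.DataFrame(out_rows).sort_values("bin_mid").reset_index(drop=True)

    for label in ("all", "diabetic", "non_diabetic"):
        p = out[f"p_{label}"]
        ok = p.notna() & (out[f"n_{label}"] > 0)
        if ok.sum() >= 4:
            x = out.loc[ok, "bin_mid"].to_numpy(dtype=float)
            w = out.loc[ok, f"n_{label}"].to_numpy(dtype=float)
            spline = make_smoothing_spline(x, p[ok].to_numpy(dtype=float),
                                           w=w, lam=smoothing_lam)
            out[f"spline_{label}"] = np.clip(spline(out["bin_mid"]), 0.0, 1.0)
        else:
            out[f"spline_{label}"] = np.nan
    return out


def _day_overlap_hours(start, end, day_start, day_end) -> float:
    lo = max(start, day_start)
    hi = min(end, day_end)
    return max((hi - lo).total_seconds(), 0.0) / 3600.0


def daily_usage(insulin: pd.DataFrame, stays: pd.DataFrame,
                max_day: int = 7) -> pd.DataFrame:
    """Daily insulin usage by kind: event counts, units, dosing probability.

    Bolus units fall on the day containing the charttime; infusion units
    are ``rate x duration`` clipped to each stay-day the infusion
    overlaps (an infusion counts as an input on every day it touches).
    The probability column conditions on the patient still being in the
    ICU that day.  ``long_acting_unit_share`` is per day, across kinds.
    """
    info = stays.set_index("icustay_id")[["intime", "outtime"]]
    kinds = ("short_bolus", "short_infusion", "intermediate", "long")
    records: dict[tuple[int, str], dict] = {
        (d, k): dict(day=d, kind=k, n_inputs=0, total_units=0.0,
                     stays_with_input=set())
        for d in range(1, max_day + 1) for k in kinds}

    for _, ev in insulin.iterrows():
        sid = ev["icustay_id"]
        if sid not in info.index:
            continue
        intime = info.at[sid, "intime"]
        kind = ev["insulin_kind"]
        if kind == "short_infusion" and pd.notna(ev.get("endtime")):
            for d in range(1, max_day + 1):
                day_start = intime + pd.Timedelta(hours=24 * (d - 1))
                day_end = intime + pd.Timedelta(hours=24 * d)
                h = _day_overlap_hours(ev["charttime"], ev["endtime"],
                                       day_start, day_end)
                if h > 0:
                    rec = records[(d, kind)]
                    rec["n_inputs"] += 1
                    rec["total_units"] += float(ev["rate"]) * h
                    rec["stays_with_input"].add(sid)
        else:
            d = int((ev["charttime"] - intime).total_seconds() // 86400) + 1
            if 1 <= d <= max_day:
                rec = records[(d, kind)]
                rec["n_inputs"] += 1
                rec["total_units"] += float(ev["amount"])
                rec["stays_with_input"].add(sid)

    los_days = ((info["outtime"] - info["intime"]).dt.total_seconds() / 86400.0)
    present_by_day = {d: int((los_days > (d - 1)).sum())
                      for d in range(1, max_day + 1)}

    rows = []
    for (d, k), rec in records.items():
        n_present = present_by_day[d]
        rows.append(dict(
            day=d, kind=k, n_inputs=rec["n_inputs"],
            total_units=round(rec["total_units"], 3),
            n_present=n_present,
            prob_any_input=(len(rec["stays_with_input"]) / n_present
                            if n_present else np.nan),
        ))
    out = pd.DataFrame(rows).sort_values(["day", "kind"]).reset_index(drop=True)
    day_units = out.groupby("day")["total_units"].transform("sum")
    with np.errstate(invalid="ignore"):
        out["unit_share"] = np.where(day_units > 0,
                                     out["total_units"] / day_units, np.nan)
    return out


def infusion_response(glucose: pd.DataFrame, insulin: pd.DataFrame,
                      hours: int = 12) -> pd.DataFrame:
    """Mean glucose by hour relative to each stay's first infusion start.

    Hour ``h`` covers ``[start + h*60, start + (h+1)*60)`` minutes for
    ``h`` in ``[-hours, hours)``.  Each stay contributes its per-hour
    mean; cells average across stays, and stays without a reading in an
    hour contribute nothing to that cell.
    """
    infusions = insulin[insulin["insulin_kind"] == "short_infusion"]
    if not len(infusions):
        warnings.warn("infusion_response: no infusions found", stacklevel=2)
        return pd.DataFrame(columns=["hour", "mean_glucose", "n_stays"])
    first = (infusions.sort_values("charttime")
             .groupby("icustay_id")["charttime"].first())

    cells: dict[int, list[float]] = {h: [] for h in range(-hours, hours)}
    for sid, start in first.items():
        grp = glucose[glucose["icustay_id"] == sid]
        if not len(grp):
            continue
        rel_h = np.floor((grp["charttime"] - start).dt.total_seconds()
                         / 3600.0).astype(int)
        for h, vals in grp.groupby(rel_h)["valuenum"]:
            if -hours <= h < hours:
                cells[h].append(float(vals.mean()))
    rows = [dict(hour=h,
                 mean_glucose=(float(np.mean(v)) if v else np.nan),
                 n_stays=len(v))
            for h, v in sorted(cells.items())]
    return pd.DataFrame(rows)
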