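"""Figure generation: per-stay timelines and daily class proportions."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .config import Thresholds
from .synthetic_emr import EMRTableSet

__all__ = ["plot_stay_timeline", "plot_daily_classes", "pick_showcase_stay"]


def pick_showcase_stay(tables: EMRTableSet):
    """The stay with the most insulin events (most informative timeline)."""
    if not len(tables.insulin):
        if not len(tables.stays):
            return None
        return tables.stays["icustay_id"].iloc[0]
    return int(tables.insulin["icustay_id"].value_counts().idxmax())


def plot_stay_timeline(stay_id, tables: EMRTableSet, path,
                       thresholds: Thresholds = Thresholds()) -> Path:
    """Glucose trace with insulin/dextrose markers and the target band."""
    stay = tables.stays[tables.stays["icustay_id"] == stay_id]
    if not len(stay):
        raise KeyError(f"unknown stay {stay_id}")
    intime = stay["intime"].iloc[0]

    def rel_hours(ts):
        return (ts - intime).dt.total_seconds() / 3600.0

    g = tables.glucose[tables.glucose["icustay_id"] == stay_id]
    ins = tables.insulin[tables.insulin["icustay_id"] == stay_id]
    dex = tables.dextrose[tables.dextrose["icustay_id"] == stay_id]

    fig, ax = plt.subplots(figsize=(10, 4))
    ax.axhspan(thresholds.hypo, thresholds.hyper, color="green", alpha=0.08,
               label=f"{thresholds.hypo:g}-{thresholds.hyper:g} mg/dL")
    if len(g):
        ax.plot(rel_hours(g["charttime"]), g["valuenum"], "o-", ms=3,
                color="tab:blue", label="glucose")
    boluses = ins[ins["insulin_kind"] == "short_bolus"]
    for _, b in boluses.iterrows():
        ax.axvline(rel_hours(pd.Series([b["charttime"]])).iloc[0],
                   color="tab:orange", alpha=0.6, lw=1)
    if len(boluses):
        ax.plot([], [], color="tab:orange", label="short-acting bolus")
    for _, inf in ins[ins["insulin_kind"] == "short_infusion"].iterrows():
        x0 = rel_hours(pd.Series([inf["charttime"]])).iloc[0]
        x1 = rel_hours(pd.Series([inf["endtime"]])).iloc[0]
        ax.axvspan(x0, x1, color="tab:red", alpha=0.15, label="infusion")
    for _, d in dex.iterrows():
        ax.plot(rel_hours(pd.Series([d["charttime"]])).iloc[0],
                thresholds.hypo, "^", color="tab:purple", ms=8)
    if len(dex):
        ax.plot([], [], "^", color="tab:purple", label="dextrose")
    ax.set_xlabel("hours since ICU admission")
    ax.set_ylabel("glucose (mg/dL)")
    ax.set_title(f"ICU stay {stay_id}")
    handles, labels = ax.get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    ax.legend(seen.values(), seen.keys(), loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)


def plot_daily_classes(daily: pd.DataFrame, path, max_day: int = 7) -> Path:
    """Stacked daily proportions of hypo / hyper / euglycaemic stay-days."""
    sub = daily[daily["day_index"] <= max_day]
    counts = (sub.groupby(["day_index", "day_class"]).size()
              .unstack(fill_value=0)
              .reindex(columns=["hypo", "hyper", "eu"], fill_value=0))
    props = counts.div(counts.sum(axis=1), axis=0)
    fig, ax = plt.subplots(figsize=(7, 4))
    props.plot.bar(stacked=True, ax=ax,
                   color={"hypo": "tab:red", "hyper": "tab:orange",
                          "eu": "tab:green"})
    ax.set_xlabel("ICU day")
    ax.set_ylabel("proportion of stay-days")
    ax.set_ylim(0, 1)
    ax.legend(title="daily class", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)
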