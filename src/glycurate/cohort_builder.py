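"""Cohort inclusion, event cleaning and note-based diabetic flagging.

The analysis unit is the ICU *stay*.  Inclusion requires adult age,
length of stay of at least 24 h, and at least one glucose measurement
charted during the stay.  Event tables are cleaned by four ordered rules
(error flag, exact duplicate, outside-stay timestamp, implausible value)
with per-rule removal counts so that every input row is accounted for as
either retained or removed-with-reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import DEFAULT_DIABETES_KEYWORDS
from .synthetic_emr import EMRTableSet, EVENT_TABLES

logger = logging.getLogger(__name__)

__all__ = [
    "CleaningReport", "select_stays", "clean_events", "clean_tables",
    "flag_diabetes", "flag_exclusion_diagnoses", "build_cohort",
    "GLUCOSE_BOUNDS", "BOLUS_DOSE_MAX",
]

#: plausible glucose range, mg/dL (exclusive bounds) — deliberately loose
GLUCOSE_BOUNDS = (10.0, 2000.0)
#: maximum plausible single bolus, units (inclusive)
BOLUS_DOSE_MAX = 100.0

EXCLUSION_DIAGNOSES = (
    "diabetic ketoacidosis",
    "beta blocker overdose",
    "hyperkalemia",
)

_CLEAN_RULES = ("error_flag", "duplicate", "unknown_stay", "outside_stay",
                "implausible")

_DUP_KEYS = {
    "glucose": ["icustay_id", "charttime", "valuenum"],
    "insulin": ["icustay_id", "charttime", "insulin_kind", "amount"],
    "dextrose": ["icustay_id", "charttime", "amount"],
    "calcium_gluconate": ["icustay_id", "charttime", "amount"],
}


@dataclass
class CleaningReport:
    """Row-removal accounting: per table, counts removed by each rule."""

    counts: dict = field(default_factory=dict)

    def add(self, table: str, rule_counts: Mapping[str, int],
            n_input: int, n_retained: int) -> None:
        removed = int(sum(rule_counts.values()))
        if removed + n_retained != n_input:
            raise AssertionError(
                f"{table}: {removed} removed + {n_retained} retained "
                f"!= {n_input} input rows")
        self.counts[table] = {"input": n_input, "retained": n_retained,
                              **{k: int(v) for k, v in rule_counts.items()}}

    def total_removed(self, table: str) -> int:
        c = self.counts[table]
        return c["input"] - c["retained"]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.counts, fh, indent=2)


def select_stays(stays: pd.DataFrame, glucose: pd.DataFrame
                 ) -> tuple[pd.DataFrame, dict]:
    """Apply the inclusion criteria to the stays table.

    Retains stays with age >= 18, length of stay >= 24 h, and at least
    one glucose measurement charted within [intime, outtime].  Exclusion
    counts are sequential, in the order: missing times, age,
    length-of-stay, glucose availability.
    """
    df = stays.copy()
    report: dict[str, int] = {}

    missing = df["intime"].isna() | df["outtime"].isna()
    for sid in df.loc[missing, "icustay_id"]:
        logger.warning("stay %s rejected: missing intime/outtime", sid)
    report["missing_times"] = int(missing.sum())
    df = df[~missing]

    under_age = df["age"] < 18.0
    report["age"] = int(under_age.sum())
    df = df[~under_age]

    short = (df["outtime"] - df["intime"]) < pd.Timedelta(hours=24)
    report["length_of_stay"] = int(short.sum())
    df = df[~short]

    g = glucose.merge(df[["icustay_id", "intime", "outtime"]], on="icustay_id")
    in_stay = g[(g["charttime"] >= g["intime"]) & (g["charttime"] <= g["outtime"])]
    has_glucose = df["icustay_id"].isin(in_stay["icustay_id"].unique())
    report["no_glucose"] = int((~has_glucose).sum())
    df = df[has_glucose]

    report["included"] = len(df)
    return df.reset_index(drop=True), report


def _implausible_mask(events: pd.DataFrame, table: str) -> pd.Series:
    if table == "glucose":
        lo, hi = GLUCOSE_BOUNDS
        return ~((events["valuenum"] > lo) & (events["valuenum"] < hi))
    if table == "insulin":
        bad = events["amount"] <= 0
        is_bolus = events["insulin_kind"] != "short_infusion"
        bad |= is_bolus & (events["amount"] > BOLUS_DOSE_MAX)
        if "rate" in events.columns:
            bad |= ~is_bolus & ~(events["rate"] > 0)
        if "endtime" in events.columns:
            bad |= ~is_bolus & ~(events["endtime"] > events["charttime"])
        return bad
    return events["amount"] <= 0  # dextrose / calcium gluconate


def clean_events(events: pd.DataFrame, stays: pd.DataFrame, table: str
                 ) -> tuple[pd.DataFrame, dict]:
    """Clean one event table; returns (retained rows, per-rule counts).

    Rules apply in order: error-flagged rows, exact duplicates (first
    occurrence in chart order kept), rows referencing an unknown stay,
    events outside the stay interval, implausible values.  Each row is
    removed by at most one rule, so counts partition the removals.
    """
    counts = dict.fromkeys(_CLEAN_RULES, 0)
    n_input = len(events)
    df = events.sort_values(
        ["charttime"] + (["row_id"] if "row_id" in events.columns else []),
        kind="stable").reset_index(drop=True)

    if "error" in df.columns:
        flagged = df["error"].fillna(0).astype(int) == 1
        counts["error_flag"] = int(flagged.sum())
        df = df[~flagged]

    dup = df.duplicated(subset=_DUP_KEYS[table], keep="first")
    counts["duplicate"] = int(dup.sum())
    df = df[~dup]

    known = stays.set_index("icustay_id")[["intime", "outtime"]]
    unknown = ~df["icustay_id"].isin(known.index)
    counts["unknown_stay"] = int(unknown.sum())
    df = df[~unknown]

    intime = df["icustay_id"].map(known["intime"])
    outtime = df["icustay_id"].map(known["outtime"])
    outside = (df["charttime"] < intime) | (df["charttime"] > outtime)
    counts["outside_stay"] = int(outside.sum())
    df = df[~outside]

    implausible = _implausible_mask(df, table)
    counts["implausible"] = int(implausible.sum())
    df = df[~implausible]

    assert sum(counts.values()) + len(df) == n_input
    return df.reset_index(drop=True), counts


def clean_tables(tables: EMRTableSet, stays: pd.DataFrame | None = None
                 ) -> tuple[EMRTableSet, CleaningReport]:
    """Clean all four event tables against the (possibly selected) stays."""
    stays = tables.stays if stays is None else stays
    report = CleaningReport()
    cleaned = {"stays": stays, "diagnoses": tables.diagnoses,
               "notes": tables.notes}
    for name in EVENT_TABLES:
        raw = getattr(tables, name)
        out, counts = clean_events(raw, stays, name)
        report.add(name, counts, len(raw), len(out))
        cleaned[name] = out
    return EMRTableSet(**cleaned), report


def flag_diabetes(notes: pd.DataFrame, stays: pd.DataFrame,
                  keywords: Iterable[str] = DEFAULT_DIABETES_KEYWORDS
                  ) -> pd.DataFrame:
    """Set the per-stay ``diabetic`` flag from free-text notes.

    A stay is flagged diabetic iff any note belonging to the stay's
    subject contains any keyword as a case-insensitive substring.  This
    reproduces the known failure mode of keyword flagging: a note saying
    "no history of diabetes" still matches "diabetes".  Stays whose
    subject has no notes are flagged False.
    """
    keywords = [k.lower() for k in keywords]
    out = stays.copy()
    if not len(notes):
        out["diabetic"] = False
        return out
    text = notes.groupby("subject_id")["text"].apply(
        lambda s: " \n ".join(s.astype(str)).lower())
    hits = text.apply(lambda t: any(k in t for k in keywords))
    out["diabetic"] = (hits.reindex(out["subject_id"])
                       .to_numpy(na_value=False).astype(bool))
    n_no_notes = int((~out["subject_id"].isin(text.index)).sum())
    if n_no_notes:
        logger.info("%d stays had no notes; flagged non-diabetic", n_no_notes)
    return out


def flag_exclusion_diagnoses(diagnoses: pd.DataFrame, stays: pd.DataFrame
                             ) -> pd.DataFrame:
    """Mark stays whose diagnoses confound insulin use.

    DKA, beta-blocker overdose and hyperkalaemia all prompt insulin for
    reasons other than routine glucose control, so their stays are
    excluded from measurement-bolus matching.
    """
    out = stays.copy()
    if not len(diagnoses):
        out["excluded_dx"] = False
        return out
    bad = diagnoses[diagnoses["diagnosis"].str.lower().isin(EXCLUSION_DIAGNOSES)]
    out["excluded_dx"] = out["icustay_id"].isin(bad["icustay_id"]).astype(bool)
    return out


def build_cohort(tables: EMRTableSet,
                 keywords: Iterable[str] = DEFAULT_DIABETES_KEYWORDS
                 ) -> tuple[EMRTableSet, dict, CleaningReport]:
    """Full curation pass: select stays, clean events, set stay flags.

    Returns the curated table set (stays carrying ``diabetic`` and
    ``excluded_dx``), the stay-exclusion report and the event-cleaning
    report.
    """
    included, stay_report = select_stays(tables.stays, tables.glucose)
    included = flag_diabetes(tables.notes, included, keywords)
    included = flag_exclusion_diagnoses(tables.diagnoses, included)
    curated, clean_report = clean_tables(tables, included)
    return curated, stay_report, clean_report
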