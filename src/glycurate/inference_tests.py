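"""Hypothesis tests on day-1 versus day-7 glycaemia.

Two questions: did the distribution of daily average glucose shift
between the first and seventh ICU day (Wilcoxon signed-rank on paired
stay averages), and did the number of stays with at least one
hypo-/hyperglycaemic event change (chi-square on 2x2 day-by-event
counts, overall and within diabetic strata, with Bonferroni correction
across the four subgroup tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TestResult", "paired_day_test", "event_count_test",
           "bonferroni_critical_p", "run_test_battery"]


def bonferroni_critical_p(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected critical p-value: alpha / number of tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class TestResult:
    name: str
    comparison: str
    statistic: float
    p_value: float
    n: int
    alpha: float
    critical_p: float
    significant: bool
    warning: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _paired_means(daily: pd.DataFrame, cohort: pd.DataFrame,
                  day_a: int, day_b: int) -> pd.DataFrame:
    sub = daily[daily["icustay_id"].isin(cohort["icustay_id"])]
    wide = sub.pivot_table(index="icustay_id", columns="day_index",
                           values="tw_mean", aggfunc="first")
    return wide[[day_a, day_b]].dropna()


def paired_day_test(daily: pd.DataFrame, cohort: pd.DataFrame,
                    day_a: int = 1, day_b: int = 7,
                    alpha: float = 0.05) -> TestResult:
    """Wilcoxon signed-rank on paired daily time-weighted averages.

    Zero differences are dropped; the normal approximation is used for
    more than 25 informative pairs, the exact distribution below that.
    Fewer than 5 informative pairs is refused.
    """
    paired = _paired_means(daily, cohort, day_a, day_b)
    diffs = (paired[day_b] - paired[day_a]).to_numpy(dtype=float)
    nonzero = diffs[diffs != 0.0]
    if len(nonzero) < 5:
        raise ValueError(
            f"paired_day_test: only {len(nonzero)} informative (nonzero) "
            "pairs; at least 5 required")
    method = "approx" if len(nonzero) > 25 else "exact"
    stat, p = stats.wilcoxon(nonzero, zero_method="wilcox", method=method)
    return TestResult(
        name="wilcoxon_signed_rank",
        comparison=f"tw_mean day {day_a} vs day {day_b}",
        statistic=float(stat), p_value=float(p), n=len(nonzero),
        alpha=alpha, critical_p=alpha, significant=bool(p < alpha),
    )


def _chi2_2x2(present_a: int, n_a: int, present_b: int, n_b: int,
              correction: bool) -> tuple[float, float, str | None]:
    table = np.array([[present_a, n_a - present_a],
                      [present_b, n_b - present_b]], dtype=float)
    if (table < 0).any() or table.sum(axis=1).min() == 0:
        raise ValueError("degenerate 2x2 table")
    res = stats.chi2_contingency(table, correction=correction)
    warning = None
    if (res.expected_freq < 5).any():
        warning = "expected cell count below 5; chi-square approximation weak"
    return float(res.statistic), float(res.pvalue), warning


def event_count_test(daily: pd.DataFrame, cohort: pd.DataFrame,
                     event_type: str, stays: pd.DataFrame,
                     day_a: int = 1, day_b: int = 7, alpha: float = 0.05,
                     n_subgroup_tests: int = 4, correction: bool = False,
                     strata: tuple[str, ...] = ("all", "diabetic",
                                                "non_diabetic"),
                     ) -> list[TestResult]:
    """Chi-square tests for a change in event prevalence between two days.

    Counts stays with at least one event of ``event_type`` on each day
    (day-specific presence already guaranteed by the cohort) and tests
    the 2x2 day-by-event table, for all stays and separately within the
    diabetic and non-diabetic subgroups.  Subgroup tests use the
    Bonferroni-corrected critical p of ``alpha / n_subgroup_tests`` —
    the correction spans both event types' subgroup tests, four in the
    default battery.  ``correction`` toggles the Yates continuity
    correction (off by default; samples here are large).
    """
    col = {"hypo": "hypo_event", "hyper": "hyper_event"}[event_type]
    flag = stays.set_index("icustay_id")["diabetic"]
    sub = daily[daily["icustay_id"].isin(cohort["icustay_id"])].copy()
    sub["diabetic"] = sub["icustay_id"].map(flag).astype(bool)

    results = []
    groups = {"all": sub, "diabetic": sub[sub["diabetic"]],
              "non_diabetic": sub[~sub["diabetic"]]}
    for label in strata:
        grp = groups[label]
        a = grp[grp["day_index"] == day_a]
        b = grp[grp["day_index"] == day_b]
        if not len(a) or not len(b):
            warnings.warn(f"event_count_test: no stays in stratum {label}",
                          stacklevel=2)
            continue
        try:
            stat, p, warn = _chi2_2x2(int(a[col].sum()), len(a),
                                      int(b[col].sum()), len(b), correction)
            significant = bool(p < (alpha if label == "all" else
                                    bonferroni_critical_p(alpha, n_subgroup_tests)))
        except ValueError:
            stat, p, significant = float("nan"), float("nan"), False
            warn = "degenerate table (a margin is zero); test undefined"
        critical = (alpha if label == "all"
                    else bonferroni_critical_p(alpha, n_subgroup_tests))
        results.append(TestResult(
            name="chi_square_2x2",
            comparison=(f"{event_type} events day {day_a} vs day {day_b} "
                        f"({label})"),
            statistic=stat, p_value=p, n=len(a) + len(b), alpha=alpha,
            critical_p=critical, significant=significant, warning=warn,
        ))
    return results


def run_test_battery(daily: pd.DataFrame, cohort: pd.DataFrame,
                     stays: pd.DataFrame, alpha: float = 0.05
                     ) -> list[TestResult]:
    """The full day-1 vs day-7 battery: Wilcoxon plus both event tests."""
    results = [paired_day_test(daily, cohort, alpha=alpha)]
    for event_type in ("hyper", "hypo"):
        results.extend(event_count_test(daily, cohort, event_type, stays,
                                        alpha=alpha))
    return results
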