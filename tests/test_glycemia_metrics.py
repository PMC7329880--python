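"""Time-weighted averaging, daily classification and recurrence risk."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glycurate import (Thresholds, daily_summaries, day1_day7_cohort,
                       generate, recurrence_hazard, table2_shares,
                       time_weighted_mean)
from conftest import make_glucose, make_stays, nonoise_config
from oracle_utils import markov_daily_events, pooled_rr_se

T0 = pd.Timestamp("2130-01-01 00:00")


def _ts(hours):
    return T0 + pd.Timedelta(hours=hours)


class TestTimeWeightedMean:
    def test_two_readings_split_day(self):
        # 100 mg/dL covers hours 0-12, 200 mg/dL covers 12-24
        got = time_weighted_mean([_ts(0), _ts(12)], [100.0, 200.0],
                                 T0, _ts(24))
        assert got == pytest.approx(150.0)

    def test_single_reading_is_its_own_mean(self):
        got = time_weighted_mean([_ts(17.3)], [137.0], T0, _ts(24))
        assert got == pytest.approx(137.0)

    def test_burst_robustness(self):
        """Ten readings of 90 within one minute then 300 for the rest of
        the day: the time-weighted mean tracks coverage, the arithmetic
        mean is dominated by the burst."""
        times = [_ts(m / 60.0) for m in range(10)] + [_ts(1 / 6)]
        values = [90.0] * 10 + [300.0]
        tw = time_weighted_mean(times, values, T0, _ts(24))
        arith = float(np.mean(values))
        assert tw > arith
        assert tw > 290.0 and arith < 110.0

    @given(st.lists(st.floats(min_value=40, max_value=400), min_size=1,
                    max_size=24))
    @settings(max_examples=50, deadline=None)
    def test_equal_spacing_equals_arithmetic_mean(self, values):
        n = len(values)
        times = [_ts(24.0 * i / n) for i in range(n)]
        tw = time_weighted_mean(times, values, T0, _ts(24))
        assert tw == pytest.approx(float(np.mean(values)), rel=1e-9)

    def test_zero_readings_refused(self):
        with pytest.raises(ValueError):
            time_weighted_mean([], [], T0, _ts(24))


class TestDailySummaries:
    stays = make_stays([(1, 1, "2130-01-01", "2130-01-09", 50.0)])

    def test_both_event_flags_can_fire(self):
        glucose = make_glucose([(1, 1, "2130-01-01 04:00", 79.0),
                                (2, 1, "2130-01-01 16:00", 181.0)])
        daily = daily_summaries(glucose, self.stays)
        row = daily.iloc[0]
        assert row["hypo_event"] and row["hyper_event"]
        assert row["day_class"] == "hypo"  # display priority

    def test_thresholds_are_strict(self):
        glucose = make_glucose([(1, 1, "2130-01-01 04:00", 80.0),
                                (2, 1, "2130-01-01 16:00", 180.0)])
        row = daily_summaries(glucose, self.stays).iloc[0]
        assert not row["hypo_event"] and not row["hyper_event"]
        assert row["day_class"] == "eu"

    def test_day_blocks_anchored_at_intime(self):
        glucose = make_glucose([(1, 1, "2130-01-01 23:00", 100.0),
                                (2, 1, "2130-01-02 01:00", 100.0)])
        daily = daily_summaries(glucose, self.stays)
        assert list(daily["day_index"]) == [1, 2]

    def test_min_tw_max_ordering(self, curated_default):
        curated, _ = curated_default
        daily = daily_summaries(curated.glucose, curated.stays)
        assert (daily["min"] <= daily["tw_mean"] + 1e-9).all()
        assert (daily["tw_mean"] <= daily["max"] + 1e-9).all()

    def test_tight_cohort_has_no_events(self):
        cfg = nonoise_config(n_stays=40, seed=91, setpoint_nondiabetic=150.0,
                             setpoint_diabetic=150.0, ou_noise_sd=5.0)
        tables, _ = generate(cfg)
        daily = daily_summaries(tables.glucose, tables.stays)
        assert not daily["hypo_event"].any()
        assert not daily["hyper_event"].any()


def test_table2_shares_nested_thresholds(curated_default):
    curated, _ = curated_default
    daily = daily_summaries(curated.glucose, curated.stays)
    shares = table2_shares(daily, curated.stays)
    for _, row in shares.iterrows():
        assert 0.0 <= row["min_below_severe_hypo"] <= row["min_below_hypo"] <= 1.0
        assert 0.0 <= row["max_above_severe_hyper"] <= row["max_above_hyper"] <= 1.0


class TestDay1Day7Cohort:
    def test_short_stay_excluded(self):
        stays = make_stays([(1, 1, "2130-01-01", "2130-01-04", 50.0)])
        glucose = make_glucose([(1, 1, "2130-01-01 06:00", 120.0),
                                (2, 1, "2130-01-03 06:00", 120.0)])
        daily = daily_summaries(glucose, stays)
        assert len(day1_day7_cohort(daily, stays)) == 0

    def test_first_stay_per_subject_kept(self):
        stays = make_stays([(1, 7, "2130-01-01", "2130-01-10", 50.0),
                            (2, 7, "2130-02-01", "2130-02-10", 50.0)])
        rows = []
        rid = 0
        for sid, start in ((1, "2130-01-01"), (2, "2130-02-01")):
            for d in (0, 6):
                rid += 1
                rows.append((rid, sid,
                             pd.Timestamp(start) + pd.Timedelta(days=d, hours=6),
                             120.0))
        daily = daily_summaries(make_glucose(rows), stays)
        cohort = day1_day7_cohort(daily, stays)
        assert list(cohort["icustay_id"]) == [1]

    def test_matches_brute_force_scan(self):
        tables, _ = generate(nonoise_config(n_stays=120, seed=44,
                                            mean_los_hours=216.0,
                                            second_stay_fraction=0.2))
        daily = daily_summaries(tables.glucose, tables.stays)
        cohort = day1_day7_cohort(daily, tables.stays)
        # oracle: direct nested scan over subjects and stays
        expected = set()
        present = daily.groupby("icustay_id")["day_index"].apply(set)
        for subj, grp in tables.stays.groupby("subject_id"):
            best = None
            for _, s in grp.iterrows():
                ds = present.get(s["icustay_id"], set())
                if 1 in ds and 7 in ds:
                    if best is None or s["intime"] < best[0]:
                        best = (s["intime"], s["icustay_id"])
            if best:
                expected.add(best[1])
        assert set(cohort["icustay_id"]) == expected


class TestRecurrenceHazard:
    def test_markov_parameter_recovery(self):
        """Pooled next-day relative risk recovers p11/p01 = 5 on chain-
        simulated daily events (2,000 stays x 7 days)."""
        rng = np.random.default_rng(12)
        daily = markov_daily_events(rng, 2000, 7, p11=0.5, p01=0.1)
        result = recurrence_hazard(daily, "hypo")
        se = pooled_rr_se(result.per_day)
        assert abs(result.pooled - 5.0) < 3 * se

    def test_no_persistence_gives_unit_ratio(self):
        rng = np.random.default_rng(5)
        daily = markov_daily_events(rng, 2000, 7, p11=0.2, p01=0.2)
        result = recurrence_hazard(daily, "hypo")
        se = pooled_rr_se(result.per_day)
        assert abs(result.pooled - 1.0) < 3 * se

    def test_event_free_cohort_degenerate(self):
        rng = np.random.default_rng(5)
        daily = markov_daily_events(rng, 50, 7, p11=0.0, p01=0.0)
        daily["hypo_event"] = False
        with pytest.warns(UserWarning):
            result = recurrence_hazard(daily, "hypo")
        assert result.pooled is None

    def test_counts_reproduce_ratio(self, curated_default):
        curated, _ = curated_default
        daily = daily_summaries(curated.glucose, curated.stays)
        result = recurrence_hazard(daily, "hyper")
        s = result.per_day[["n11", "n10", "n01", "n00"]].sum()
        manual = (s["n11"] / (s["n11"] + s["n10"])) / \
                 (s["n01"] / (s["n01"] + s["n00"]))
        assert result.pooled == pytest.approx(manual)
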