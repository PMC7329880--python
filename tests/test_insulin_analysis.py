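"""Dose-given-glucose analyses: regression, heat map, bolus-probability
curves, daily usage and infusion response."""

import numpy as np
import pandas as pd
import pytest

from glycurate import (DoseRegressionResult, MatchWindow, bolus_probability,
                       build_cohort, daily_usage, dose_heatmap,
                       exclude_confounded, fit_dose_regression, generate,
                       infusion_response, match)
from glycurate.config import ConfigError
from glycurate.event_matching import annotate_diabetic
from conftest import make_boluses, make_glucose, make_stays, nonoise_config


def planar_pairs(b0, b1, b2, b3, n=200, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    g = rng.uniform(80, 400, n)
    d = (rng.random(n) < 0.4).astype(float)
    dose = b0 + b1 * g + d * (b2 + b3 * g) + rng.normal(0, noise, n)
    return pd.DataFrame({"glucose_mgdl": g, "diabetic": d.astype(bool),
                         "dose_units": dose})


class TestDoseRegression:
    def test_noiseless_plane_recovered_to_machine_precision(self):
        coefs = (-1.53, 0.0308, 0.1685, -0.0004)
        fit = fit_dose_regression(planar_pairs(*coefs))
        for got, want in zip(
                (fit.params[c] for c in ("const", "glucose", "diabetic",
                                         "glucose_x_diabetic")), coefs):
            assert got == pytest.approx(want, abs=1e-8)
        assert round(fit.predict(200, diabetic=True), 2) == 4.72

    def test_constant_dose_flat_fit(self):
        pairs = planar_pairs(0, 0, 0, 0)
        pairs["dose_units"] = 6.0
        fit = fit_dose_regression(pairs)
        assert fit.params["const"] == pytest.approx(6.0, abs=1e-10)
        for c in ("glucose", "diabetic", "glucose_x_diabetic"):
            assert fit.params[c] == pytest.approx(0.0, abs=1e-10)

    def test_prediction_table_is_affine_in_coefficients(self):
        fit = DoseRegressionResult.from_coefficients(-1.53, 0.0308,
                                                     0.1685, -0.0004)
        table = fit.prediction_table()
        by = {(r["glucose_mgdl"], r["stratum"]): r["predicted_dose_units"]
              for _, r in table.iterrows()}
        assert by[(200.0, "non_diabetic")] == pytest.approx(-1.53 + 0.0308 * 200, abs=0.005)
        assert by[(200.0, "diabetic")] == 4.72
        # affine check: diabetic minus non-diabetic equals b2 + b3*g
        assert by[(400.0, "diabetic")] - by[(400.0, "non_diabetic")] == \
            pytest.approx(0.1685 - 0.0004 * 400, abs=0.01)

    def test_degenerate_designs_rejected(self):
        pairs = planar_pairs(0, 0.03, 0, 0, n=50)
        with pytest.raises(ConfigError, match="10 matched pairs"):
            fit_dose_regression(pairs.head(5))
        const_g = pairs.copy()
        const_g["glucose_mgdl"] = 200.0
        with pytest.raises(ConfigError, match="glucose"):
            fit_dose_regression(const_g)
        one_stratum = pairs.copy()
        one_stratum["diabetic"] = True
        with pytest.raises(ConfigError, match="diabetic"):
            fit_dose_regression(one_stratum)

    def test_sliding_scale_slope_recovery(self):
        """The fitted glucose slope agrees, within 3 robust SEs, with the
        slope of an OLS fit to the noise-free policy doses at the same
        matched glucose values (the generative dose-response)."""
        cfg = nonoise_config(n_stays=400, seed=61, dose_noise_sd=0.75,
                             omission_prob=0.1)
        tables, truth = generate(cfg)
        curated, _, _ = build_cohort(tables)
        retained, _ = exclude_confounded(curated.insulin, curated.stays,
                                         curated.calcium_gluconate)
        pairs, _ = match(retained, curated.glucose)
        pairs = annotate_diabetic(pairs, curated.stays)
        fit = fit_dose_regression(pairs)
        # oracle slope: regress the deterministic scale dose on glucose
        g = pairs["glucose_mgdl"].to_numpy()
        policy = np.select([g > 350, g > 300, g > 250, g > 200],
                           [8.0, 6.0, 4.0, 2.0], default=0.0)
        slope_true = np.polyfit(g, policy, 1)[0]
        assert abs(fit.params["glucose"] - slope_true) < \
            3 * fit.robust_se["glucose"]


class TestDoseHeatmap:
    def test_single_cell(self):
        pairs = pd.DataFrame({"glucose_mgdl": [200.0] * 5,
                              "dose_units": [4.0] * 5})
        heat = dose_heatmap(pairs)
        col = heat.probabilities.iloc[:, 0]
        assert col.max() == 1.0 and col.sum() == pytest.approx(1.0)

    def test_columns_normalized_over_random_inputs(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pairs = pd.DataFrame({
                "glucose_mgdl": rng.uniform(50, 450, 300),
                "dose_units": rng.integers(0, 20, 300).astype(float)})
            heat = dose_heatmap(pairs)
            sums = heat.probabilities.sum(axis=0, skipna=True)
            nonempty = heat.column_counts > 0
            assert np.allclose(sums[nonempty.to_numpy()], 1.0)

    def test_scale_cohort_mass_on_scale_dose(self, nonoise_sim):
        tables, truth = nonoise_sim
        curated, _, _ = build_cohort(tables)
        pairs, _ = match(curated.insulin, curated.glucose)
        heat = dose_heatmap(pairs, glucose_bin_width=50.0, dose_bin_width=2.0)
        # glucose in [200,250) maps to the 2-unit scale band -> dose bin [2,4)
        col = heat.probabilities["[200,250)"]
        assert col.loc["[2,4)"] == pytest.approx(1.0)


class TestBolusProbability:
    def test_step_policy_recovered(self, nonoise_sim):
        tables, _ = nonoise_sim
        curated, _, _ = build_cohort(tables)
        curve = bolus_probability(curated.glucose, curated.insulin,
                                  curated.stays)
        below = curve[curve["bin_mid"] < 175.0]
        above = curve[(curve["bin_mid"] > 225.0) & (curve["n_all"] >= 20)]
        assert (below["p_all"] < 0.05).all()
        assert (above["p_all"] > 0.9).all()

    def test_omission_plateau(self):
        cfg = nonoise_config(n_stays=300, seed=71, omission_prob=0.3)
        tables, _ = generate(cfg)
        curated, _, _ = build_cohort(tables)
        curve = bolus_probability(curated.glucose, curated.insulin,
                                  curated.stays)
        plateau = curve[(curve["bin_mid"] > 225.0) & (curve["n_all"] >= 50)]
        assert plateau["p_all"].mean() == pytest.approx(0.7, abs=0.05)

    def test_same_policy_strata_agree(self, nonoise_sim):
        tables, _ = nonoise_sim
        curated, _, _ = build_cohort(tables)
        curve = bolus_probability(curated.glucose, curated.insulin,
                                  curated.stays)
        both = curve[(curve["n_diabetic"] >= 25)
                     & (curve["n_non_diabetic"] >= 25)
                     & (curve["bin_mid"] < 300.0)]
        assert len(both) > 0
        for _, row in both.iterrows():
            p = row["p_all"]
            se = np.sqrt(max(p * (1 - p), 0.01)
                         * (1 / row["n_diabetic"] + 1 / row["n_non_diabetic"]))
            assert abs(row["p_diabetic"] - row["p_non_diabetic"]) < 4 * se


class TestDailyUsage:
    stays = make_stays([(1, 1, "2130-01-01", "2130-01-08", 50.0)])

    def test_single_bolus_day_placement(self):
        ins = make_boluses([(1, 1, "2130-01-02 10:00", 4.0)])
        usage = daily_usage(ins, self.stays)
        by = usage.set_index(["day", "kind"])
        assert by.loc[(2, "short_bolus"), "prob_any_input"] == 1.0
        assert by.loc[(1, "short_bolus"), "prob_any_input"] == 0.0
        assert by.loc[(2, "short_bolus"), "total_units"] == 4.0

    def test_infusion_units_clipped_per_day(self):
        ins = make_boluses([(1, 1, "2130-01-01 20:00", 16.0)],
                           kind="short_infusion")
        ins["endtime"] = pd.Timestamp("2130-01-02 04:00")
        ins["rate"] = 2.0
        usage = daily_usage(ins, self.stays)
        by = usage.set_index(["day", "kind"])["total_units"]
        assert by.loc[(1, "short_infusion")] == pytest.approx(8.0)
        assert by.loc[(2, "short_infusion")] == pytest.approx(8.0)

    def test_no_long_acting_share_zero(self):
        ins = make_boluses([(1, 1, "2130-01-02 10:00", 4.0)])
        usage = daily_usage(ins, self.stays)
        long_rows = usage[usage["kind"] == "long"]
        day2 = usage[(usage["day"] == 2) & (usage["kind"] == "long")]
        assert (day2["unit_share"] == 0.0).all()
        assert (long_rows["total_units"] == 0.0).all()

    def test_unit_shares_sum_to_one(self, curated_default):
        curated, _ = curated_default
        usage = daily_usage(curated.insulin, curated.stays)
        sums = usage.groupby("day")["unit_share"].sum()
        active = usage.groupby("day")["total_units"].sum() > 0
        assert np.allclose(sums[active], 1.0)


class TestInfusionResponse:
    def test_post_initiation_decline_toward_target(self):
        cfg = nonoise_config(n_stays=400, seed=83, setpoint_sd=25.0,
                             omission_prob=1.0)  # no boluses; drips only
        tables, _ = generate(cfg)
        resp = infusion_response(tables.glucose, tables.insulin)
        # hours 0-4: the drip is still running for nearly every stay
        # (later hours mix in post-infusion rebound and drop-out)
        post = resp[(resp["hour"] >= 0) & (resp["hour"] <= 4)
                    & (resp["n_stays"] >= 5)]
        assert len(post) >= 4
        means = post.sort_values("hour")["mean_glucose"].to_numpy()
        assert (np.diff(means) < 5.0).all()  # monotone within sampling noise
        assert means[-1] < means[0] - 50.0
        pre = resp[(resp["hour"] == -1)]
        assert pre["mean_glucose"].iloc[0] > 250.0

    def test_no_readings_after_start_gives_nulls(self):
        ins = make_boluses([(1, 1, "2130-01-02 00:00", 8.0)],
                           kind="short_infusion")
        ins["endtime"] = pd.Timestamp("2130-01-02 04:00")
        ins["rate"] = 2.0
        glucose = make_glucose([(1, 1, "2130-01-01 23:00", 300.0)])
        resp = infusion_response(glucose, ins)
        assert resp.loc[resp["hour"] == -1, "n_stays"].iloc[0] == 1
        assert (resp.loc[resp["hour"] >= 0, "n_stays"] == 0).all()
        assert resp.loc[resp["hour"] >= 0, "mean_glucose"].isna().all()

    def test_only_first_infusion_used(self):
        ins = make_boluses([(1, 1, "2130-01-02 00:00", 8.0),
                            (2, 1, "2130-01-03 00:00", 8.0)],
                           kind="short_infusion")
        ins["endtime"] = ins["charttime"] + pd.Timedelta(hours=4)
        ins["rate"] = 2.0
        glucose = make_glucose([(1, 1, "2130-01-02 01:00", 250.0),
                                (2, 1, "2130-01-03 01:00", 150.0)])
        resp = infusion_response(glucose, ins)
        assert resp.loc[resp["hour"] == 1, "mean_glucose"].iloc[0] == 250.0

    def test_no_infusions_warns(self):
        with pytest.warns(UserWarning):
            resp = infusion_response(make_glucose([]), make_boluses([]))
        assert len(resp) == 0
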