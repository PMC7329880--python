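import pandas as pd
import pytest

from glycurate import SimConfig, build_cohort, generate
from glycurate.config import ConfounderRates


def make_stays(rows):
    """Build a stays table from (icustay_id, subject_id, intime, outtime,
    age) tuples; unit/admission filled with constants."""
    df = pd.DataFrame(rows, columns=["icustay_id", "subject_id", "intime",
                                     "outtime", "age"])
    df["intime"] = pd.to_datetime(df["intime"], format="mixed")
    df["outtime"] = pd.to_datetime(df["outtime"], format="mixed")
    df["first_careunit"] = "MICU"
    df["admission_type"] = "EMERGENCY"
    return df


def make_glucose(rows):
    """Glucose table from (row_id, icustay_id, charttime, valuenum)."""
    df = pd.DataFrame(rows, columns=["row_id", "icustay_id", "charttime",
                                     "valuenum"])
    df["charttime"] = pd.to_datetime(df["charttime"], format="mixed")
    df["subject_id"] = df["icustay_id"]
    df["error"] = 0
    return df


def make_boluses(rows, kind="short_bolus"):
    """Insulin table from (row_id, icustay_id, charttime, amount)."""
    df = pd.DataFrame(rows, columns=["row_id", "icustay_id", "charttime",
                                     "amount"])
    df["charttime"] = pd.to_datetime(df["charttime"], format="mixed")
    df["subject_id"] = df["icustay_id"]
    df["endtime"] = pd.NaT
    df["rate"] = float("nan")
    df["insulin_kind"] = kind
    df["error"] = 0
    return df


def nonoise_config(**overrides) -> SimConfig:
    """A deterministic-policy regime: no dose omission or noise, exact
    (unrounded) charting, no confounders or decoy notes."""
    base = dict(n_stays=200, seed=202, omission_prob=0.0, dose_noise_sd=0.0,
                timestamp_rounding_minutes=0.0, decoy_note_rate=0.0,
                second_stay_fraction=0.0, setpoint_sd=0.0,
                confounder_rates=ConfounderRates())
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def default_sim():
    """A realistic-regime cohort with all defaults."""
    return generate(SimConfig(n_stays=150, seed=101))


@pytest.fixture(scope="session")
def curated_default(default_sim):
    tables, truth = default_sim
    curated, stay_report, clean_report = build_cohort(tables)
    return curated, truth


@pytest.fixture(scope="session")
def nonoise_sim():
    return generate(nonoise_config())
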