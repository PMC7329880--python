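"""Synthetic ICU EMR generator with known ground truth.

Emits event tables in the MIMIC column dialect (``subject_id``,
``icustay_id``, ``charttime``, value columns) together with a
:class:`SimTruth` sidecar that records the generative parameters of every
stay, the true causal (measurement, bolus) links, and pre-rounding event
timestamps.  The truth object is never consumed by the analysis pipeline;
it exists so that every downstream stage — cleaning, matching, dose
regression, recurrence estimation — can be scored against a known answer.

Generative model
----------------
Latent glucose for each stay is a discretized Ornstein-Uhlenbeck process
on a 5-minute grid around a setpoint that depends on diabetic status,
plus a deterministic "deviation" channel that carries treatment effects:
each administered insulin unit subtracts ``sensitivity`` mg/dL with
exponential washout, dextrose adds a bump the same way, and an active
insulin infusion relaxes glucose toward a target with a configurable time
constant.  Measurements sample the latent path every
``measurement_interval_hours`` (hourly while an infusion runs) and drive
a sliding-scale bolus policy mirroring standard ICU practice: a reading
above the lowest scale threshold triggers, with probability
``1 - omission_prob``, a short-acting bolus charted 0-60 minutes later at
the scale dose plus noise, its charttime rounded to the nearest hour the
way bedside charting rounds timestamps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import ConfigError, SimConfig

__all__ = ["EMRTableSet", "SimTruth", "generate", "corrupt"]

BASE_TIME = pd.Timestamp("2130-01-01 00:00:00")  # de-identified-style epoch

EVENT_TABLES = ("glucose", "insulin", "dextrose", "calcium_gluconate")

_UNITS = np.array(["MICU", "CCU", "SICU"])
_UNIT_P = np.array([0.42, 0.12, 0.46])
_ADMIT = np.array(["EMERGENCY", "ELECTIVE"])
_ADMIT_P = np.array([0.86, 0.14])

_GENERIC_SENTENCES = (
    "Patient admitted to the ICU for close monitoring.",
    "Hemodynamically stable overnight.",
    "Plan: continue supportive care and serial labs.",
    "Family meeting held to discuss goals of care.",
)
_DECOY_SENTENCE = "no history of diabetes"


@dataclass
class EMRTableSet:
    """The seven MIMIC-dialect tables the pipeline consumes."""

    stays: pd.DataFrame
    glucose: pd.DataFrame
    insulin: pd.DataFrame
    dextrose: pd.DataFrame
    calcium_gluconate: pd.DataFrame
    diagnoses: pd.DataFrame
    notes: pd.DataFrame

    def to_csv_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for f in dc_fields(self):
            getattr(self, f.name).to_csv(outdir / f"{f.name}.csv", index=False)

    @classmethod
    def from_csv_dir(cls, indir) -> "EMRTableSet":
        indir = Path(indir)
        kwargs = {}
        for f in dc_fields(cls):
            df = pd.read_csv(indir / f"{f.name}.csv")
            for col in ("intime", "outtime", "charttime", "endtime"):
                if col in df.columns:
                    df[col] = pd.to_datetime(df[col])
            kwargs[f.name] = df
        return cls(**kwargs)


@dataclass
class SimTruth:
    """Ground truth: generative parameters and causal event links.

    ``links`` has one row per policy-caused bolus, referencing the
    emitted ``row_id`` of both the bolus and its triggering measurement
    with exact (pre-rounding) timestamps.  ``defects`` is filled by
    :func:`corrupt` and lists every injected defect row so cleaning can
    be scored exactly.
    """

    stays: pd.DataFrame
    links: pd.DataFrame
    exact_times: pd.DataFrame
    defects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["table", "row_id", "defect"])
    )

    def to_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.stays.to_csv(outdir / "truth_stays.csv", index=False)
        self.links.to_csv(outdir / "truth_links.csv", index=False)
        self.exact_times.to_csv(outdir / "truth_exact_times.csv", index=False)
        self.defects.to_csv(outdir / "truth_defects.csv", index=False)


def _round_time(ts_minutes: float, rounding_minutes: float) -> float:
    """Round a minute offset to the charting resolution (0 = exact)."""
    if rounding_minutes <= 0:
        return ts_minutes
    return round(ts_minutes / rounding_minutes) * rounding_minutes


def _scale_dose(value: float, scale) -> float:
    """Dose for the highest sliding-scale band at or below ``value``."""
    dose = 0.0
    for threshold, units in scale:
        if value > threshold:
            dose = units
    return dose


def _ou_path(rng, n: int, setpoint: float, theta: float, sd: float, dt: float):
    """Exact AR(1) discretization of an OU process, stationary start."""
    a = math.exp(-theta * dt)
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - a * a), size=n)
    x0 = rng.normal(setpoint, sd)
    dev, _ = lfilter([1.0], [1.0, -a], innov, zi=[a * (x0 - setpoint)])
    return setpoint + dev


class _DeviationLedger:
    """Treatment-effect channel: impulses with exponential washout."""

    def __init__(self, half_life_hours: float):
        self.lam = math.log(2.0) / (half_life_hours * 60.0)  # per minute
        self.events: list[tuple[float, float]] = []  # (t_minutes, delta mg/dL)

    def add(self, t: float, delta: float) -> None:
        self.events.append((t, delta))

    def at(self, t: float) -> float:
        return sum(
            d * math.exp(-self.lam * (t - te)) for te, d in self.events if te <= t
        )


def generate(config: SimConfig) -> tuple[EMRTableSet, SimTruth]:
    """Simulate ICU stays and their charted events.

    Returns the seven-table :class:`EMRTableSet` plus a :class:`SimTruth`
    sidecar.  Fully deterministic under ``config.seed``.
    """
    if not isinstance(config, SimConfig):
        raise ConfigError("generate() requires a SimConfig")
    rng = np.random.default_rng(config.seed)

    n_second = int(round(config.second_stay_fraction * config.n_stays / 2.0))
    n_subjects = config.n_stays - n_second

    # subject-level draws
    subj_age = np.clip(rng.normal(65.0, 16.0, n_subjects), 18.0, 95.0)
    subj_diab = rng.random(n_subjects) < config.diabetic_fraction

    stay_rows, gluc_rows, ins_rows, dex_rows, cal_rows = [], [], [], [], []
    dx_rows, note_rows = [], []
    truth_stay_rows, link_rows, exact_rows = [], [], []
    gid = iid = did = cid = 0  # per-table row_id counters

    lowest_threshold = config.sliding_scale[0][0]
    stay_id = 0
    for s in range(n_subjects):
        subject_id = 10000 + s
        n_stays_subj = 2 if s < n_second else 1
        next_intime = BASE_TIME + pd.Timedelta(days=float(rng.uniform(0, 365)))
        for k in range(n_stays_subj):
            stay_id += 1
            icustay_id = 200000 + stay_id
            los_h = max(26.0, rng.gamma(2.0, config.mean_los_hours / 2.0))
            intime = next_intime
            outtime = intime + pd.Timedelta(hours=los_h)
            next_intime = outtime + pd.Timedelta(days=float(rng.uniform(5, 60)))

            diabetic = bool(subj_diab[s])
            base_setpoint = (
                config.setpoint_diabetic if diabetic else config.setpoint_nondiabetic
            )
            # between-patient heterogeneity: individual glycaemic anchors
            setpoint = float(np.clip(
                rng.normal(base_setpoint, config.setpoint_sd), 80.0, 320.0))
            sens = max(2.0, rng.normal(config.insulin_sensitivity_mean,
                                       config.insulin_sensitivity_sd))
            stay_rows.append(dict(
                icustay_id=icustay_id, subject_id=subject_id, intime=intime,
                outtime=outtime, age=round(float(subj_age[s]), 1),
                first_careunit=str(rng.choice(_UNITS, p=_UNIT_P)),
                admission_type=str(rng.choice(_ADMIT, p=_ADMIT_P)),
            ))
            truth_stay_rows.append(dict(
                icustay_id=icustay_id, subject_id=subject_id, diabetic=diabetic,
                setpoint=setpoint, sensitivity=sens,
            ))

            # latent OU path on the fine grid
            dt_h = config.latent_step_minutes / 60.0
            n_grid = int(math.ceil(los_h / dt_h)) + 1
            path = _ou_path(rng, n_grid, setpoint, config.ou_reversion_rate,
                            config.ou_noise_sd, dt_h)
            ledger = _DeviationLedger(config.insulin_half_life_hours)

            # infusion state
            inf_active = False
            inf_start_min = inf_start_g = 0.0
            inf_runs: list[tuple[float, float]] = []  # (start_min, end_min)
            consec_high = 0
            tau_min = config.infusion_time_constant_hours * 60.0

            def latent_at(t_min: float) -> float:
                idx = min(int(t_min / config.latent_step_minutes), n_grid - 1)
                g = path[idx] + ledger.at(t_min)
                if inf_active and t_min >= inf_start_min:
                    g += (config.infusion_target - inf_start_g) * (
                        1.0 - math.exp(-(t_min - inf_start_min) / tau_min)
                    )
                return g

            los_min = los_h * 60.0
            t_meas = float(rng.uniform(30.0, config.measurement_interval_hours * 60.0))
            while t_meas < los_min:
                g = latent_at(t_meas)
                value = float(np.round(np.clip(g, 15.0, 1200.0)))
                gid += 1
                meas_row_id = gid
                gluc_rows.append(dict(
                    row_id=meas_row_id, subject_id=subject_id,
                    icustay_id=icustay_id,
                    charttime=intime + pd.Timedelta(minutes=t_meas),
                    valuenum=value, error=0,
                ))

                # infusion state updates first: persistent severe
                # hyperglycaemia starts a drip, which replaces scale dosing
                if inf_active:
                    if value < config.infusion_trigger and t_meas - inf_start_min >= 240.0:
                        inf_runs.append((inf_start_min, t_meas))
                        # freeze the achieved correction into the washout channel
                        ledger.add(t_meas, (config.infusion_target - inf_start_g) * (
                            1.0 - math.exp(-(t_meas - inf_start_min) / tau_min)))
                        inf_active = False
                        consec_high = 0
                else:
                    if value > config.infusion_trigger:
                        consec_high += 1
                        if consec_high >= config.infusion_persistence:
                            inf_active = True
                            inf_start_min = t_meas + float(rng.uniform(0.0, 30.0))
                            inf_start_g = latent_at(t_meas)
                    else:
                        consec_high = 0

                # sliding-scale bolus policy (suspended while an infusion
                # runs; no dosing past discharge)
                if (value > lowest_threshold and not inf_active
                        and rng.random() >= config.omission_prob):
                    dose = _scale_dose(value, config.sliding_scale)
                    dose = max(0.0, dose + rng.normal(0.0, config.dose_noise_sd))
                    dose = float(round(dose))
                    lag = float(rng.uniform(0.0, 60.0))
                    t_true = t_meas + lag
                    if dose > 0 and t_true < los_min:
                        t_chart = min(_round_time(
                            t_true, config.timestamp_rounding_minutes), los_min)
                        iid += 1
                        ins_rows.append(dict(
                            row_id=iid, subject_id=subject_id,
                            icustay_id=icustay_id,
                            charttime=intime + pd.Timedelta(minutes=t_chart),
                            endtime=pd.NaT, amount=dose, rate=np.nan,
                            insulin_kind="short_bolus", error=0,
                        ))
                        link_rows.append(dict(
                            bolus_row_id=iid, glucose_row_id=meas_row_id,
                            icustay_id=icustay_id,
                            true_lag_minutes=lag,
                        ))
                        exact_rows.append(dict(
                            table="insulin", row_id=iid,
                            true_charttime=intime + pd.Timedelta(minutes=t_true),
                        ))
                        ledger.add(t_true, -sens * dose)

                # dextrose rescue for hypoglycaemia
                if value < config.dextrose_trigger and t_meas + 30.0 < los_min:
                    t_true = t_meas + float(rng.uniform(0.0, 30.0))
                    t_chart = min(_round_time(
                        t_true, config.timestamp_rounding_minutes), los_min)
                    did += 1
                    dex_rows.append(dict(
                        row_id=did, subject_id=subject_id, icustay_id=icustay_id,
                        charttime=intime + pd.Timedelta(minutes=t_chart),
                        amount=25.0, error=0,
                    ))
                    exact_rows.append(dict(
                        table="dextrose", row_id=did,
                        true_charttime=intime + pd.Timedelta(minutes=t_true),
                    ))
                    ledger.add(t_true, config.dextrose_effect_mgdl)

                # hourly monitoring during infusion, 4-hourly otherwise
                step = 60.0 if inf_active else config.measurement_interval_hours * 60.0
                t_meas += step

            if inf_active and inf_start_min < los_min:
                inf_runs.append((inf_start_min, los_min))
            for start_min, end_min in inf_runs:
                dur_h = (end_min - start_min) / 60.0
                if dur_h <= 0:
                    continue
                iid += 1
                ins_rows.append(dict(
                    row_id=iid, subject_id=subject_id, icustay_id=icustay_id,
                    charttime=intime + pd.Timedelta(minutes=start_min),
                    endtime=intime + pd.Timedelta(minutes=end_min),
                    amount=round(config.infusion_rate_units_per_hour * dur_h, 2),
                    rate=config.infusion_rate_units_per_hour,
                    insulin_kind="short_infusion", error=0,
                ))

            # basal insulin for diabetics (no latent feedback: modelled as
            # maintaining the setpoint rather than perturbing it)
            if diabetic:
                day = 0
                while day * 1440.0 + 480.0 < los_min:  # 08:00 each stay-day
                    t_min = day * 1440.0 + 480.0
                    if rng.random() < 0.5:
                        iid += 1
                        ins_rows.append(dict(
                            row_id=iid, subject_id=subject_id,
                            icustay_id=icustay_id,
                            charttime=intime + pd.Timedelta(minutes=t_min),
                            endtime=pd.NaT,
                            amount=float(max(4, round(rng.normal(20.0, 4.0)))),
                            rate=np.nan, insulin_kind="long", error=0,
                        ))
                    if rng.random() < 0.05:
                        iid += 1
                        ins_rows.append(dict(
                            row_id=iid, subject_id=subject_id,
                            icustay_id=icustay_id,
                            charttime=intime + pd.Timedelta(minutes=t_min + 60.0),
                            endtime=pd.NaT,
                            amount=float(max(2, round(rng.normal(10.0, 3.0)))),
                            rate=np.nan, insulin_kind="intermediate", error=0,
                        ))
                    day += 1

            # confounder diagnoses and calcium gluconate
            cr = config.confounder_rates
            for dx, p in (("diabetic ketoacidosis", cr.dka),
                          ("beta blocker overdose", cr.beta_blocker_overdose),
                          ("hyperkalemia", cr.hyperkalemia)):
                if rng.random() < p:
                    dx_rows.append(dict(subject_id=subject_id,
                                        icustay_id=icustay_id, diagnosis=dx))
            if rng.random() < cr.calcium_gluconate:
                for _ in range(int(rng.integers(1, 4))):
                    cid += 1
                    cal_rows.append(dict(
                        row_id=cid, subject_id=subject_id, icustay_id=icustay_id,
                        charttime=intime + pd.Timedelta(
                            minutes=float(rng.uniform(0.0, los_min))),
                        amount=2.0, error=0,
                    ))

            # clinical note
            sentences = list(rng.choice(_GENERIC_SENTENCES, size=2, replace=False))
            if diabetic:
                kw = str(rng.choice(np.array(config.diabetes_keywords, dtype=object)))
                sentences.insert(1, f"Past medical history notable for {kw}.")
            elif rng.random() < config.decoy_note_rate:
                sentences.insert(1, f"Patient has {_DECOY_SENTENCE}.")
            note_rows.append(dict(
                subject_id=subject_id, icustay_id=icustay_id,
                charttime=intime + pd.Timedelta(hours=12.0),
                text=" ".join(sentences),
            ))

    def _frame(rows, columns):
        df = pd.DataFrame(rows, columns=columns)
        if "charttime" in columns and len(df):
            df = df.sort_values(
                ["charttime"] + (["row_id"] if "row_id" in columns else []),
                kind="stable").reset_index(drop=True)
        return df

    tables = EMRTableSet(
        stays=pd.DataFrame(stay_rows),
        glucose=_frame(gluc_rows, ["row_id", "subject_id", "icustay_id",
                                   "charttime", "valuenum", "error"]),
        insulin=_frame(ins_rows, ["row_id", "subject_id", "icustay_id",
                                  "charttime", "endtime", "amount", "rate",
                                  "insulin_kind", "error"]),
        dextrose=_frame(dex_rows, ["row_id", "subject_id", "icustay_id",
                                   "charttime", "amount", "error"]),
        calcium_gluconate=_frame(cal_rows, ["row_id", "subject_id",
                                            "icustay_id", "charttime",
                                            "amount", "error"]),
        diagnoses=pd.DataFrame(dx_rows, columns=["subject_id", "icustay_id",
                                                 "diagnosis"]),
        notes=pd.DataFrame(note_rows, columns=["subject_id", "icustay_id",
                                               "charttime", "text"]),
    )
    truth = SimTruth(
        stays=pd.DataFrame(truth_stay_rows),
        links=pd.DataFrame(link_rows, columns=["bolus_row_id", "glucose_row_id",
                                               "icustay_id", "true_lag_minutes"]),
        exact_times=pd.DataFrame(exact_rows, columns=["table", "row_id",
                                                      "true_charttime"]),
    )
    return tables, truth


_DEFECTS = ("error_flag", "duplicate", "outside_stay", "implausible")


def corrupt(tables: EMRTableSet, error_rate: float, seed: int
            ) -> tuple[EMRTableSet, pd.DataFrame]:
    """Inject charting defects into the event tables at the given rate.

    Each event row is independently selected with probability
    ``error_rate``; a selected row receives one defect drawn uniformly
    from: its error flag set, an exact duplicate appended, a copy
    timestamped outside the stay interval, or a copy with a
    physiologically implausible value.  Returns the corrupted tables and
    a provenance ledger (``table``, ``row_id``, ``defect``) naming every
    row that event cleaning should remove.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ConfigError("error_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    stays = tables.stays.set_index("icustay_id")
    out = {"stays": tables.stays.copy(), "diagnoses": tables.diagnoses.copy(),
           "notes": tables.notes.copy()}
    ledger_rows = []

    for name in EVENT_TABLES:
        df = getattr(tables, name).copy()
        if not len(df):
            out[name] = df
            continue
        next_id = int(df["row_id"].max()) + 1
        picked = np.flatnonzero(rng.random(len(df)) < error_rate)
        new_rows = []
        for pos in picked:
            defect = _DEFECTS[int(rng.integers(0, len(_DEFECTS)))]
            row = df.iloc[pos]
            if defect == "error_flag":
                df.iat[pos, df.columns.get_loc("error")] = 1
                ledger_rows.append((name, int(row["row_id"]), defect))
                continue
            copy = row.copy()
            copy["row_id"] = next_id
            if defect == "outside_stay":
                outt = stays.at[int(row["icustay_id"]), "outtime"]
                copy["charttime"] = outt + pd.Timedelta(
                    hours=float(rng.uniform(1.0, 48.0)))
            elif defect == "implausible":
                if name == "glucose":
                    copy["valuenum"] = float(rng.choice([0.0, -5.0, 2500.0, 4000.0]))
                elif name == "insulin" and row.get("insulin_kind") != "short_infusion":
                    copy["amount"] = float(rng.choice([0.0, 250.0, 1000.0]))
                else:
                    copy["amount"] = float(rng.choice([0.0, -5.0]))
            new_rows.append(copy)
            ledger_rows.append((name, next_id, defect))
            next_id += 1
        if new_rows:
            df = pd.concat([df, pd.DataFrame(new_rows)], ignore_index=True)
            df = df.sort_values(["charttime", "row_id"], kind="stable"
                                ).reset_index(drop=True)
        out[name] = df

    ledger = pd.DataFrame(ledger_rows, columns=["table", "row_id", "defect"])
    return EMRTableSet(**out), ledger
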