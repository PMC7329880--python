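"""Configuration objects shared across the pipeline stages.

All tunable thresholds live here: the glycaemia classification cut-offs,
the bolus-to-measurement matching window, and the parameters of the
synthetic EMR generator.  Each dataclass validates its invariants in
``__post_init__`` and raises :class:`ConfigError` on violation, so a bad
YAML file fails loudly before any data is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its documented invariants."""


@dataclass(frozen=True)
class Thresholds:
    """Glycaemia classification cut-offs in mg/dL.

    ``hypo`` and ``hyper`` use strict inequalities: a reading of exactly
    180 mg/dL is not hyperglycaemic and a reading of exactly 80 mg/dL is
    not hypoglycaemic.  The target band is the range insulin-infusion
    protocols steer toward.
    """

    hypo: float = 80.0
    hyper: float = 180.0
    severe_hypo: float = 50.0
    severe_hyper: float = 200.0
    target_low: float = 140.0
    target_high: float = 180.0

    def __post_init__(self) -> None:
        ok = (
            self.severe_hypo < self.hypo <= self.target_low
            <= self.target_high <= self.hyper < self.severe_hyper
        )
        if not ok:
            raise ConfigError(
                "threshold ordering must satisfy severe_hypo < hypo <= "
                "target_low <= target_high <= hyper < severe_hyper, got "
                f"{self}"
            )


@dataclass(frozen=True)
class MatchWindow:
    """Temporal window for pairing an insulin bolus with its trigger.

    ``before`` minutes look back from the bolus charttime (charting lag:
    the measurement usually precedes the dose) and ``after`` minutes look
    forward (events occasionally charted in the opposite order).  Both
    boundaries are inclusive.
    """

    before: float = 60.0
    after: float = 10.0

    def __post_init__(self) -> None:
        if self.before < 0 or self.after < 0:
            raise ConfigError("window extents must be non-negative")
        if self.before + self.after <= 0:
            raise ConfigError("window must have positive total width")


#: (threshold mg/dL, dose units) bands of the default weight-based sliding
#: scale: dose increases incrementally as glucose exceeds each threshold.
DEFAULT_SLIDING_SCALE: tuple[tuple[float, float], ...] = (
    (200.0, 2.0),
    (250.0, 4.0),
    (300.0, 6.0),
    (350.0, 8.0),
)

DEFAULT_DIABETES_KEYWORDS: tuple[str, ...] = (
    "diabetes",
    "diabetes mellitus",
    "insulin dependent",
)


@dataclass(frozen=True)
class ConfounderRates:
    """Per-stay probabilities of matching-confounder conditions."""

    dka: float = 0.0
    beta_blocker_overdose: float = 0.0
    hyperkalemia: float = 0.0
    calcium_gluconate: float = 0.0

    def __post_init__(self) -> None:
        for name, p in asdict(self).items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"confounder rate {name}={p} outside [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic EMR generator.

    Glucose follows a per-stay mean-reverting (Ornstein-Uhlenbeck)
    process around a diabetic-status-dependent setpoint; a sliding-scale
    dosing policy reacts to measurements, and each administered unit
    lowers subsequent glucose by the stay's insulin sensitivity with
    exponential washout.

    Notes on units: ``ou_reversion_rate`` is per hour, ``ou_noise_sd`` is
    the *stationary* standard deviation of the latent process in mg/dL,
    and ``insulin_sensitivity_mean``/``sd`` are mg/dL drop per unit.
    """

    n_stays: int = 200
    seed: int = 0
    mean_los_hours: float = 96.0
    diabetic_fraction: float = 0.24
    setpoint_nondiabetic: float = 135.0
    setpoint_diabetic: float = 175.0
    setpoint_sd: float = 25.0
    ou_reversion_rate: float = 0.2
    ou_noise_sd: float = 35.0
    measurement_interval_hours: float = 4.0
    timestamp_rounding_minutes: float = 60.0
    insulin_sensitivity_mean: float = 15.0
    insulin_sensitivity_sd: float = 5.0
    insulin_half_life_hours: float = 2.0
    sliding_scale: tuple[tuple[float, float], ...] = DEFAULT_SLIDING_SCALE
    dose_noise_sd: float = 0.75
    omission_prob: float = 0.1
    infusion_trigger: float = 280.0
    infusion_persistence: int = 1
    infusion_rate_units_per_hour: float = 4.0
    infusion_target: float = 150.0
    infusion_time_constant_hours: float = 4.0
    dextrose_trigger: float = 70.0
    dextrose_effect_mgdl: float = 40.0
    confounder_rates: ConfounderRates = field(default_factory=ConfounderRates)
    diabetes_keywords: tuple[str, ...] = DEFAULT_DIABETES_KEYWORDS
    decoy_note_rate: float = 0.0
    second_stay_fraction: float = 0.1
    latent_step_minutes: float = 5.0

    def __post_init__(self) -> None:
        if self.n_stays <= 0:
            raise ConfigError("n_stays must be positive")
        if self.mean_los_hours <= 0 or self.measurement_interval_hours <= 0:
            raise ConfigError("durations must be positive")
        if self.latent_step_minutes <= 0:
            raise ConfigError("latent_step_minutes must be positive")
        for name in ("diabetic_fraction", "omission_prob", "decoy_note_rate",
                     "second_stay_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.setpoint_diabetic < self.setpoint_nondiabetic:
            raise ConfigError(
                "setpoint_diabetic must be >= setpoint_nondiabetic"
            )
        thr = [t for t, _ in self.sliding_scale]
        if not thr or any(b <= a for a, b in zip(thr, thr[1:])):
            raise ConfigError("sliding-scale thresholds must be strictly increasing")
        if self.ou_reversion_rate <= 0 or self.ou_noise_sd < 0:
            raise ConfigError("OU parameters out of range")
        object.__setattr__(
            self, "sliding_scale", tuple((float(t), float(d)) for t, d in self.sliding_scale)
        )
        object.__setattr__(self, "diabetes_keywords", tuple(self.diabetes_keywords))


def _coerce(cls, data: dict):
    if cls is SimConfig and "confounder_rates" in data and isinstance(
        data["confounder_rates"], dict
    ):
        data = dict(data)
        data["confounder_rates"] = ConfounderRates(**data["confounder_rates"])
    if cls is SimConfig and "sliding_scale" in data:
        data = dict(data)
        data["sliding_scale"] = tuple(tuple(x) for x in data["sliding_scale"])
    return cls(**data)


def load_yaml_config(path, cls=SimConfig):
    """Instantiate a config dataclass from a YAML mapping file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    return _coerce(cls, data)


def dump_yaml_config(cfg, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
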