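"""Stage orchestration with a reproducibility manifest.

``run_pipeline`` chains the stages (optional synthetic generation →
cohort curation → bolus matching → glycaemia summaries → hypothesis
tests → figures) and writes a manifest recording the configuration, the
content hash of every tabular artifact and per-stage row counts.  The
manifest contains no timestamps or absolute paths, so two runs with the
same configuration and seed produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cohort_builder, event_matching, glycemia_metrics, \
    inference_tests, insulin_analysis
from .config import ConfigError, MatchWindow, SimConfig, Thresholds
from .synthetic_emr import EMRTableSet, generate

logger = logging.getLogger(__name__)

ALL_STAGES = ("generate", "build_cohort", "match", "summarize", "analyze",
              "report")


@dataclass
class PipelineConfig:
    """End-to-end run configuration; one object controls every stage."""

    output_dir: str
    input_dir: str | None = None          # required unless generating
    sim: SimConfig | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    window: MatchWindow = field(default_factory=MatchWindow)
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if "generate" not in self.stages and self.input_dir is None:
            raise ConfigError("input_dir required when not generating")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    A stage failure aborts the run with the stage name and the row
    counts accumulated so far attached to the raised exception.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            "seed": config.seed,
            "stages": list(config.stages),
            "thresholds": dataclasses.asdict(config.thresholds),
            "window": dataclasses.asdict(config.window),
            "sim": dataclasses.asdict(config.sim) if config.sim else None,
        },
        "artifacts": {},
        "row_counts": {},
    }

    def record(stage: str, path: Path, n_rows: int | None = None) -> None:
        rel = path.name
        manifest["artifacts"].setdefault(stage, {})[rel] = (
            _sha256(path) if path.suffix in {".csv", ".json"} else "figure")
        if n_rows is not None:
            manifest["row_counts"].setdefault(stage, {})[rel] = n_rows

    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, out, state, record)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage '{stage}' failed "
                f"(row counts so far: {manifest['row_counts']})") from exc

    _write_json(manifest, out / "manifest.json")
    return manifest


def _stage_generate(config, out, state, record):
    if config.sim is None:
        raise ConfigError("generate stage requires a SimConfig")
    sim = dataclasses.replace(config.sim, seed=config.seed)
    tables, truth = generate(sim)
    raw_dir = out / "raw"
    tables.to_csv_dir(raw_dir)
    truth.to_dir(out / "truth")
    for name in ("stays", "glucose", "insulin", "dextrose",
                 "calcium_gluconate", "diagnoses", "notes"):
        record("generate", raw_dir / f"{name}.csv",
               len(getattr(tables, name)))
    state["tables"] = tables


def _load_inputs(config, state) -> EMRTableSet:
    if "tables" not in state:
        indir = Path(config.input_dir)
        if not indir.is_dir():
            raise ConfigError(f"input directory does not exist: {indir}")
        state["tables"] = EMRTableSet.from_csv_dir(indir)
    return state["tables"]


def _stage_build_cohort(config, out, state, record):
    tables = _load_inputs(config, state)
    curated, stay_report, clean_report = cohort_builder.build_cohort(tables)
    state["curated"] = curated
    cur_dir = out / "curated"
    curated.to_csv_dir(cur_dir)
    _write_json(stay_report, out / "stay_exclusions.json")
    clean_report.to_json(out / "cleaning_report.json")
    record("build_cohort", out / "stay_exclusions.json")
    record("build_cohort", out / "cleaning_report.json")
    for name in ("stays", "glucose", "insulin"):
        record("build_cohort", cur_dir / f"{name}.csv",
               len(getattr(curated, name)))


def _stage_match(config, out, state, record):
    curated: EMRTableSet = state["curated"]
    retained, drop_counts = event_matching.exclude_confounded(
        curated.insulin, curated.stays, curated.calcium_gluconate)
    pairs, unmatched = event_matching.match(retained, curated.glucose,
                                            config.window)
    pairs = event_matching.annotate_diabetic(pairs, curated.stays)
    rate = event_matching.match_rate(pairs, retained, curated.glucose,
                                     curated.stays)
    state["pairs"] = pairs
    pairs.to_csv(out / "matched_pairs.csv", index=False)
    _write_json({"confounder_drops": drop_counts, **rate},
                out / "match_rate.json")
    record("match", out / "matched_pairs.csv", len(pairs))
    record("match", out / "match_rate.json")


def _stage_summarize(config, out, state, record):
    curated: EMRTableSet = state["curated"]
    daily = glycemia_metrics.daily_summaries(curated.glucose, curated.stays,
                                             config.thresholds)
    cohort = glycemia_metrics.day1_day7_cohort(daily, curated.stays)
    shares = glycemia_metrics.table2_shares(daily, curated.stays,
                                            thresholds=config.thresholds)
    hazards = {et: glycemia_metrics.recurrence_hazard(daily, et)
               for et in ("hypo", "hyper")}
    state.update(daily=daily, cohort=cohort)
    daily.to_csv(out / "daily_glycemia.csv", index=False)
    shares.to_csv(out / "table2_shares.csv", index=False)
    _write_json({et: {"pooled": hr.pooled, "mean_rr": hr.mean_rr,
                      "per_day": hr.per_day.to_dict(orient="records")}
                 for et, hr in hazards.items()},
                out / "hazard_ratios.json")
    record("summarize", out / "daily_glycemia.csv", len(daily))
    record("summarize", out / "table2_shares.csv", len(shares))
    record("summarize", out / "hazard_ratios.json")


def _stage_analyze(config, out, state, record):
    curated: EMRTableSet = state["curated"]
    results = inference_tests.run_test_battery(state["daily"],
                                               state["cohort"],
                                               curated.stays)
    _write_json([r.to_dict() for r in results], out / "tests.json")
    record("analyze", out / "tests.json", len(results))

    pairs = state.get("pairs")
    if pairs is not None and len(pairs) >= 10:
        try:
            reg = insulin_analysis.fit_dose_regression(pairs)
            _write_json({
                "params": reg.params, "robust_se": reg.robust_se,
                "p_values": reg.p_values, "cov_type": reg.cov_type,
                "n_obs": reg.n_obs, "caveat": reg.caveat,
                "predictions": reg.prediction_table().to_dict(orient="records"),
            }, out / "dose_regression.json")
            record("analyze", out / "dose_regression.json")
        except ConfigError as exc:
            logger.warning("dose regression skipped: %s", exc)
        heat = insulin_analysis.dose_heatmap(pairs)
        heat.probabilities.to_csv(out / "dose_heatmap.csv")
        record("analyze", out / "dose_heatmap.csv", len(heat.probabilities))
    curve = insulin_analysis.bolus_probability(curated.glucose,
                                               curated.insulin,
                                               curated.stays, config.window)
    curve.to_csv(out / "bolus_probability.csv", index=False)
    record("analyze", out / "bolus_probability.csv", len(curve))
    usage = insulin_analysis.daily_usage(curated.insulin, curated.stays)
    usage.to_csv(out / "daily_usage.csv", index=False)
    record("analyze", out / "daily_usage.csv", len(usage))
    resp = insulin_analysis.infusion_response(curated.glucose, curated.insulin)
    resp.to_csv(out / "infusion_response.csv", index=False)
    record("analyze", out / "infusion_response.csv", len(resp))


def _stage_report(config, out, state, record):
    from . import plotting
    curated: EMRTableSet = state["curated"]
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    sid = plotting.pick_showcase_stay(curated)
    if sid is not None:
        path = fig_dir / f"stay_timeline_{sid}.png"
        plotting.plot_stay_timeline(sid, curated, path,
                                    thresholds=config.thresholds)
        record("report", path)
    if "daily" in state:
        path = fig_dir / "daily_class_proportions.png"
        plotting.plot_daily_classes(state["daily"], path)
        record("report", path)


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "build_cohort": _stage_build_cohort,
    "match": _stage_match,
    "summarize": _stage_summarize,
    "analyze": _stage_analyze,
    "report": _stage_report,
}
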