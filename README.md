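# glycurate

Curation and characterization of blood-glucose control and insulin use
in the intensive care unit, from raw EMR event tables.

ICU records chart glucose measurements and insulin doses as *unlinked*
events, with hour-rounded timestamps, duplicates, error-flagged rows and
out-of-stay entries.  `glycurate` turns a set of MIMIC-dialect CSV
tables (ICU stays, glucose measurements, insulin / dextrose /
calcium-gluconate inputs, diagnoses, free-text notes) into the standard
descriptive battery for glycaemic management:

* **Cohort curation** — adult stays ≥ 24 h with ≥ 1 glucose reading;
  ordered event-cleaning rules with full removal accounting; keyword
  diabetic flagging from notes.
* **Event matching** — each short-acting bolus is paired with the most
  recent glucose reading in a −60/+10 minute window (inclusive), after
  dropping insulin confounded by DKA / beta-blocker overdose /
  hyperkalaemia diagnoses or nearby calcium-gluconate inputs.
* **Daily glycaemia** — per stay-day time-weighted (LOCF) average,
  min/max, and event classification (hypo < 80 mg/dL, hyper >
  180 mg/dL, strict; severe at 50/200), with next-day recurrence
  relative risks RR = P(event d+1 | event d) / P(event d+1 | no event
  d) pooled over day pairs.
* **Insulin analyses** — dose-given-glucose heat map; OLS of dose on
  glucose × diabetic status with robust (HC1) standard errors and
  predicted doses; spline-smoothed bolus-probability curves; daily
  usage by insulin kind; glucose trajectory ±12 h around infusion
  starts.
* **Hypothesis tests** — Wilcoxon signed-rank on paired day-1/day-7
  averages and 2×2 chi-square event-count tests with Bonferroni
  correction (critical p = α/4) across subgroup tests.
* **Synthetic EMR generator** — a per-stay Ornstein–Uhlenbeck glucose
  model with a sliding-scale dosing policy, infusions, dextrose
  rescues, hour-rounded charting and an injectable-defect `corrupt()`
  stage, all with a ground-truth sidecar so every pipeline stage is
  testable without access to restricted clinical data.

## Worked example

Run the whole pipeline on a 300-stay synthetic cohort:

```python
import json
import glycurate as gc

cfg = gc.PipelineConfig(output_dir="demo", sim=gc.SimConfig(n_stays=300),
                        seed=42)
gc.run_pipeline(cfg)

mr = json.load(open("demo/match_rate.json"))
hz = json.load(open("demo/hazard_ratios.json"))
print("match rate %.3f (%d/%d boluses)" % (mr["rate"], mr["n_matched"],
                                           mr["n_boluses"]))
print("pooled RR hypo %.2f hyper %.2f" % (hz["hypo"]["pooled"],
                                          hz["hyper"]["pooled"]))
```

prints

```
match rate 0.803 (511/636 boluses)
pooled RR hypo 3.46 hyper 2.25
```

About 80% of charted boluses find a triggering measurement — the ~20%
loss is what hour-rounded charting does to a −60/+10 minute window.  A
stay with a hypoglycaemic day is ~3.5× as likely as a well-controlled
stay to be hypoglycaemic again the next day (≈2.3× for
hyperglycaemia): abnormal control persists.  `demo/` also contains
`daily_glycemia.csv`, `table2_shares.csv` (shares of stays with
abnormal daily averages/extremes by day and diabetic stratum),
`matched_pairs.csv`, `dose_regression.json`, `tests.json`, per-stay
timeline figures, and a `manifest.json` of content hashes that is
byte-identical across reruns with the same seed.

The same stages are available from the shell:

```sh
glycurate generate --out data --seed 42
glycurate run --in data/raw --out demo --seed 42
```

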