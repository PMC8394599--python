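# ansq — autonomic nervous system quantification

`ansq` quantifies autonomic nervous system (ANS) function from multichannel
physiological recordings. Five bedside autonomic tests (squat, cold pressor,
deep breathing, diving reflex, Valsalva maneuver) perturb heart rate, blood
pressure, and heart-rate variability; `ansq` extracts each individual's
baseline-normalized responses, compares them to cohort-average response
templates, and summarizes every response with two interpretable features:

- **H** — a duration scale (how much slower/faster than the template), and
- **V = Vs + Vo** — an amplitude (scale `Vs` plus offset `Vo`).

Features are classified as primarily sympathetic (S) or parasympathetic (P)
and aggregated into four per-participant indices (S-H, S-V, P-H, P-V) that
can be correlated with covariates such as BMI and validated by repeated
k-fold cross-validation.

A first-class synthetic-data generator produces both cohort-level response
traces and full raw 1 kHz sessions (ECG, continuous blood pressure,
respiration, EDA, pupil + gaze) with known ground truth, so every stage of
the pipeline can be verified end to end.

## Worked example

Simulate a cohort with a known BMI effect on sympathetic amplitude, extract
features, and recover the effect:

```python
import numpy as np
from ansq import (simulate_cohort, features_from_traces, classify_features,
                  linear_regression_pvalue, repeated_kfold_cv_mape)

# 1. Simulate 21 subjects x 4 sessions of squat-descent MAP responses.
#    Sympathetic amplitude follows alpha + beta * BMI with beta = 0.05.
cell = ("squat", "squat", "MAP")
traces, truth = simulate_cohort(cells=[cell], beta=0.05, seed=1)

# 2. Build the cohort-average template, apply the 1-sigma significance
#    gate, and fit the four-parameter transform to every trace.
table, templates = features_from_traces(traces, gate_sigma=truth.noise_sigma)
print(table.head())          # H, Vs, Vo, V, b_delay, objective per trace

# 3. Classify features into S/P branches and average per subject.
labeled = classify_features(table)
sv = labeled[labeled["group"] == "S-V"]
means = sv.groupby("subject_id")["value"].mean()
bmi = np.array([truth.subjects[s]["bmi"] for s in means.index])

# 4. Regression of the sympathetic amplitude index on BMI ...
res = linear_regression_pvalue(bmi, means.to_numpy())
print(f"slope {res.slope:.3f} (true 0.05), p = {res.p_value:.2e}")

# 5. ... validated by 10 repeats of 7-fold CV predicting BMI from the index.
cv = repeated_kfold_cv_mape(means.to_numpy(), bmi, repeats=10, folds=7)
print(f"MAPE {cv.mean_mape:.1f}% +/- {cv.sd_mape:.2f}")
```

Or drive the whole pipeline from the command line:

```sh
# write a YAML config
cat > cfg.yaml <<'YAML'
mode: traces
seed: 1
out_dir: run1
cells: [[squat, squat, MAP]]
YAML
ansq run --config cfg.yaml      # feature_table.csv, report.json, ...
ansq report --run-dir run1

# synthesize a raw 1 kHz session and inspect it
ansq simulate --out session1 --tests squat,diving_reflex --seed 7
```

## Package layout

| module | role |
| --- | --- |
| `ansq.signal_io` | raw channel files, session manifests, feature tables |
| `ansq.preprocess` | R-peak detection, HR/RMSSD/MAP/EDA/pupil derivation |
| `ansq.protocol` | the five test definitions, epochs, baselines |
| `ansq.template` | cohort-average templates + 1σ significance gate |
| `ansq.matching` | four-parameter template transform fitting (H, V) |
| `ansq.indices` | S/P classification rules and participant aggregation |
| `ansq.stats` | regression p-values, repeated k-fold CV (MAPE) |
| `ansq.synthetic` | cohort- and raw-session generators with ground truth |
| `ansq.pipeline` | end-to-end runner (`RunConfig` → artifacts + report) |
| `ansq.cli` | `ansq simulate / run / regress / crossval / report` |

See `docs/methods.md` for the method in detail and `examples/` for
narrative scripts. `scripts/acceptance.py --seed 1 --out out.json` computes
the release-gate quantities.

## Testing

```sh
python -m pytest -q tests/
```

Unit and property tests run in seconds; `tests/test_acceptance.py` contains
the longer release criteria (simulation studies, ~15 min total).
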