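#!/bin/sh
# End-to-end pipeline from the command line.
#
# Runs the traces-mode pipeline from a YAML config, prints the report, and
# re-runs the statistics stages on the written artifacts.
#
# Run:  sh examples/03_cli_pipeline.sh
set -e

WORK=$(mktemp -d)
echo "working in $WORK"

cat > "$WORK/cfg.yaml" <<'YAML'
mode: traces
seed: 1
n_subjects: 21
sessions_per_subject: 4
cells: [[squat, squat, MAP]]
cv_repeats: 10
cv_folds: 7
YAML

ansq run --config "$WORK/cfg.yaml" --out "$WORK/run"
ansq report --run-dir "$WORK/run"

# the run wrote per-subject summaries; redo the statistics standalone
python - "$WORK" <<'PY'
import sys, pandas as pd
from pathlib import Path
work = Path(sys.argv[1])
# covariates come from the run log in traces mode; for the standalone
# commands we rebuild them from the simulation truth
from ansq import simulate_cohort
_, truth = simulate_cohort(cells=[("squat", "squat", "MAP")], seed=1)
pd.DataFrame([{"subject_id": s, **{"bmi": d["bmi"]}}
              for s, d in truth.subjects.items()]
             ).to_csv(work / "covariates.csv", index=False)
PY

ansq regress  --summary "$WORK/run/participant_summary.csv" \
              --covariates "$WORK/covariates.csv" --group S-V
ansq crossval --summary "$WORK/run/participant_summary.csv" \
              --covariates "$WORK/covariates.csv" --group S-V --seed 1
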