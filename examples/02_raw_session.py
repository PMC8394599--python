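"""From a raw 1 kHz recording to fitted response features.

Synthesizes one raw session (ECG, blood pressure, respiration, ...) with a
known squat-test response, then walks the preprocessing chain explicitly:
notch -> R peaks -> derived signals -> baselines -> epochs -> template fit.

Run:  python examples/02_raw_session.py
"""

import warnings

import numpy as np

from ansq import (canonical_template, compute_heart_rate, compute_map_series,
                  detect_r_peaks, fit_template, make_session_manifest,
                  notch_filter, simulate_raw_session)
from ansq.pipeline import extract_session_traces

# --- 1. synthesize a session ----------------------------------------------
# Inject a squat-descent MAP response that is 20% slower and 30% larger
# than the canonical template; everything else stays at rest.
truth = {("squat", "squat", "MAP"):
         dict(duration=1.2, delay=0.0, amplitude=1.3, offset=0.0)}
manifest = make_session_manifest(tests=["squat"])
rec = simulate_raw_session(truth, manifest, line_noise_mv=0.1, seed=42)
print(f"session: {rec.n_samples / rec.fs:.0f} s at {rec.fs:.0f} Hz, "
      f"channels {sorted(rec.channels)}")

# --- 2. preprocess by hand (the pipeline does all of this internally) -----
ecg = notch_filter(rec.channels["ECG"], rec.fs)  # remove the 60 Hz mains
beats = detect_r_peaks(ecg, rec.fs)
hr = compute_heart_rate(beats)
mp = compute_map_series(notch_filter(rec.channels["BP"], rec.fs),
                        rec.fs, beats)
print(f"{beats.n_beats} beats, resting HR {np.median(hr.v):.1f} bpm, "
      f"resting MAP {np.median(mp.v):.1f} mmHg")

# --- 3. epochs + baseline normalization -----------------------------------
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # quiet modalities warn and are skipped
    traces, baselines = extract_session_traces(rec, manifest)
print(f"extracted {len(traces)} epoch traces; baselines for "
      f"{sorted(baselines)}")

# --- 4. fit the injected cell against its template -------------------------
tr = next(t for t in traces
          if (t.test, t.epoch, t.modality) == ("squat", "squat", "MAP"))
res = fit_template(canonical_template("squat", "squat", "MAP"), tr)
print(f"\nfitted: duration {1 / res.a:.3f} (true 1.2), "
      f"amplitude {res.c:.3f} (true 1.3), "
      f"V = {res.V:.3f}, objective {res.objective:.3f}")
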