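# Methods

This document describes what `ansq` computes and the design decisions made
where the method leaves room for interpretation.

## 1. Signals and preprocessing

Raw sessions are multichannel recordings at a common sampling rate
(default 1 kHz): ECG (mandatory), continuous blood pressure (mandatory),
respiration, EDA, pupil diameter, and the RGB color of the gaze location.
A session manifest records the subject, session index (1–4), time of day
(AM/PM), covariates, and the protocol event times.

Derived signals (4 Hz unless noted):

- **HR** — R peaks are detected on the band-passed (5–25 Hz), squared,
  moving-window-integrated ECG; inter-beat intervals (IBIs) outside
  250–3000 ms or deviating more than 30% from an 11-beat running median
  are rejected as artifacts. Instantaneous HR = 60000/IBI, assigned at the
  closing beat and interpolated to a uniform grid.
- **RMSSD** — root mean square of successive IBI differences over a 60 s
  sliding window stepped at 1 s. Differences are only taken between
  adjacent beats (artifact gaps do not bridge). Not computed for the cold
  pressor test or the Valsalva maneuver (their analysis intervals are
  shorter than the window).
- **MAP** — the mean of the blood-pressure waveform over each beat,
  assigned at the beat midpoint.
- **EDA** — low-passed at 1 Hz. EDA enters only the significance gate; in
  healthy cohorts it fails the gate and is excluded.
- **Pupil** — gaze RGB is converted to relative luminance
  L = (0.2126·R + 0.7152·G + 0.0722·B)/255, pupil diameter is regressed on
  L, and the pupil series is divided by the fitted slope to remove the
  luminance-driven scale. Like EDA, pupil responses are gate-checked but
  not feature-extracted.
- A 60 Hz notch (Q = 30, zero-phase) is applied to ECG and BP before any
  detection.

## 2. Protocol, epochs, baselines

Five tests with fixed epochs on a 4 Hz grid (time 0 = the epoch's anchor
event):

| test | epochs |
| --- | --- |
| squat | squat (60 s), stand (60 s) |
| cold pressor | hand_in (60 s), hand_out (60 s) |
| deep breathing | first_2min (120 s of the paced period) |
| diving reflex | mask_on (60 s), mask_off (60 s) |
| Valsalva | inhale (5 s), vm (15 s), release (10 s), recovery (60 s) |

Each test's baseline is a 60 s sitting window ending 5 s before the test's
first event, shrunk (to a minimum of 30 s) if a preceding test leaves less
room. Epoch samples are baseline-normalized as fractional change
y = (v − μ)/μ. Samples beyond the end of the recording are filled by
holding the last value and flagged; template averaging excludes them and
fitting restricts the objective to observed samples.

## 3. Templates and the significance gate

For every (test, epoch, modality) the normalized traces of all subjects
and sessions are averaged pointwise into the template f(x) anchored at x0.
A template is **significant** iff its peak deviation exceeds one pooled
baseline standard deviation (σ pooled as the RMS of the per-session
normalized baseline SDs). The gate is two-sided by default so bradycardic
(downward) responses such as diving-reflex HR are retained. Modalities
failing the gate are excluded from feature extraction; their rows appear
in the feature table flagged `gated` with empty features.

## 4. Template matching (the H and V features)

Each individual trace y(x) is matched by the four-parameter transform

    g(x) = c · f(a(x − x0) + x0 − b) + d

minimizing the normalized objective

    J(a, b, c, d) = ‖g − y‖² / VAR(g)

where VAR is the population variance of g over the observed samples; a
flat g gives J = +∞. Reported features: duration H = 1/a by default (a > 1
compresses the template, so 1/a is the response's duration multiple; the
`literal_a` convention reports H = a instead), delay b, amplitude
Vs = c, offset Vo = d, V = Vs + Vo.

Optimization: for fixed (a, b) the optimal (c, d) have a closed form —
with ũ, ỹ the centered warped template and trace,
c\* = ‖ỹ‖²/(ũ·ỹ), d\* = mean(y) − c\*·mean(u), and the profiled objective
is N(1 − r²). Multi-start Nelder–Mead therefore searches only (a, b)
(starts a ∈ {0.5, 1, 2} × b ∈ {−5, 0, 5} s plus a coarse grid pre-search),
with a bounded 4-D polish whenever the profiled (c\*, d\*) violate their
bounds (a ∈ [0.2, 5], |b| ≤ half the epoch, c ∈ [−5, 5], d ∈ [−1, 1]).
A `brute_force_fit` grid oracle exists solely for verification.

### Known estimator properties

- **Noise inflates the amplitude.** The profiled c\* = ‖ỹ‖²/(ũ·ỹ) is the
  inverse-regression estimator: white noise of variance σ² on the trace
  inflates its expectation by roughly the noise-to-template-variance ratio
  σ²/VAR(c·f). At the generator's default noise (σ = 0.1 × template peak)
  the bias is ≈ 10% for typical shapes; at substantially larger σ the
  single-trace amplitude degrades quickly. This is a property of the
  normalized-SSE objective itself, not of the optimizer.
- **Saturating shapes trade amplitude for duration.** On plateau-like
  responses (e.g. the cold-pressor pressor response) a longer duration and
  a smaller amplitude produce nearly identical curves within the epoch, so
  fitted amplitudes are systematically attenuated (observed slope ≈ 0.042
  per kg/m² when 0.05 was injected). Cohort-level effect sizes measured on
  such cells are conservative. Unimodal (gamma-pulse) cells do not show
  this trade-off.

### Deep breathing

Paced breathing entrains every subject to the same cycle timing, so no
duration feature exists for this test. The feature is the mean peak-to-
trough HR excursion per breathing cycle (segmented from the respiration
channel when available, else fixed 10 s windows), normalized by the cohort
mean excursion; cohort-mean V is therefore exactly 1.

## 5. Classification and indices

Each gated-in (test, epoch, modality) feature is labeled sympathetic (S)
or parasympathetic (P) by an editable rule table (YAML round-trip;
`ansq.indices.DEFAULT_RULES`). Pressor/tachycardic responses are S;
bradycardic and HRV responses are P. Special cases: in the squat stand
epoch only V is S and only H (plus RMSSD H) is P; deep breathing
contributes a single V feature to P; cold-pressor HR is not assigned.
Features aggregate per participant into four indices — S-H, S-V, P-H,
P-V — as mean ± SD over sessions, optionally split AM/PM.

## 6. Statistics

Per-subject index means are regressed on a covariate (default BMI) by OLS;
significance is the two-sided t-test on the slope (n − 2 df). Validation
is repeated k-fold cross-validation (default 10 repeats of 7 folds,
subjects reshuffled each repeat): the trend line fitted on training
subjects is inverted to predict the held-out subjects' covariate, and
accuracy is reported as mean absolute percentage error (MAPE) per repeat.

## 7. Synthetic data

`simulate_cohort` draws a cohort (default n = 21, BMI ~ N(24.4, 2.9²),
age ~ N(29.9, 6.5²), 16 M / 5 F, four sessions: two AM, two PM). Each of
19 canonical response shapes (gamma pulses, plateaus, biphasic and sine
shapes with physiologic signs and time constants) is warped per
subject-session with truth recorded: sympathetic-cell amplitude
α + β·BMI + ε (default β = 0.05, between-subject SD 0.12, between-session
SD 0.10), log-normal duration, Gaussian delay and offset, and white trace
noise with per-cell σ = 0.1 × the template's peak magnitude — the same
convention used in the robustness simulations (an absolute `noise_sigma`
can override it). Defaults were fixed a priori by a power analysis
(slope t ≈ 5 at n = 21).

`simulate_raw_session` renders cell-level truth into a full 1 kHz session:
the HR curve drives beat times by integration; ECG is a Gaussian R spike +
T bump per beat; BP is a per-beat pulse whose beat mean equals the target
MAP exactly; respiration is paced at 6/min during deep breathing and
15/min otherwise; optional beat-to-beat jitter realizes RMSSD truth and
optional 60 Hz contamination exercises the notch. Each response is
linearly tapered to zero over 20 s past its epoch so the raw signal is
continuous — consequently an epoch immediately following an injected one
inherits some of its tail, which end-to-end recovery checks avoid by
injecting truth only into non-adjacent primary epochs.

## 8. Acceptance harness

`scripts/acceptance.py --seed S --out report.json` recomputes the
release-gate quantities (identity fit, 200-draw parameter recovery per
template both noise-free and at σ = 0.1 × peak, brute-force oracle
comparison, closed-form signal checks, gate behavior and monotonicity,
raw-session inverse crime, 100-repeat cohort β recovery plus a β = 0 null
calibration, and structure counts) and writes them under descriptive
names. The cohort repeats use the single identifiable gamma-pulse cell
(squat descent MAP, 84 template fits per repeat) so the check measures
recovery rather than the plateau attenuation documented above.
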