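"""Synthetic sessions and cohorts with known ground truth.

Every stage of the pipeline is testable without human data: canonical
response shapes stand in for the cohort-average templates, individual
responses are generated by applying the template transform with known
(duration, delay, amplitude, offset) plus additive Gaussian noise, and full
1 kHz multichannel raw sessions can be synthesized so that preprocessing,
epoching and matching are exercised end to end against the injected truth.

Canonical shapes are parameterized pulse kernels on the epoch grid:

* ``gamma`` — a unimodal (t/τ)^k·exp(k(1−t/τ)) pulse peaking at τ;
* ``plateau`` — a saturating (1 − exp(−t/τ))² rise (sustained pressor
  responses);
* ``bigamma`` — difference of two gamma pulses (biphasic Valsalva
  hemodynamics);
* ``sine`` — paced-breathing heart-rate oscillation at 6 cycles/min.

Directions follow physiology: bradycardic (negative HR) diving response,
positive pressor (MAP) cold response, transient HR rise on standing. Peak
amplitudes are 0.1–0.3 in baseline-normalized units.

The cohort generator links the amplitude of sympathetically classified
responses to body mass index, amplitude = α + β·BMI + ε, so downstream
regression and cross-validation can be checked for calibration (β = 0) and
recovery (β > 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError, DataError
from .indices import DEFAULT_RULES
from .preprocess import DERIVED_FS
from .protocol import EPOCH_FS, Epoch, ResponseTrace, TEST_DEFINITIONS, get_test
from .signal_io import Recording, SessionManifest
from .template import Template

__all__ = [
    "ShapeSpec",
    "SHAPES",
    "GroundTruth",
    "make_template_shape",
    "canonical_template",
    "canonical_template_keys",
    "simulate_response",
    "simulate_cohort",
    "make_session_manifest",
    "simulate_raw_session",
]


@dataclass(frozen=True)
class ShapeSpec:
    kind: str  # gamma | plateau | bigamma | sine
    amp: float
    tau: float = 10.0
    k: float = 2.0
    amp2: float = 0.0
    tau2: float = 20.0
    k2: float = 2.0
    freq: float = 0.1

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "gamma":
            return self.amp * _gamma_pulse(t, self.tau, self.k)
        if self.kind == "plateau":
            x = np.clip(t / self.tau, 0.0, None)
            return self.amp * (1.0 - np.exp(-x)) ** 2
        if self.kind == "bigamma":
            return (self.amp * _gamma_pulse(t, self.tau, self.k)
                    + self.amp2 * _gamma_pulse(t, self.tau2, self.k2))
        if self.kind == "sine":
            return self.amp * np.sin(2 * np.pi * self.freq * np.clip(t, 0, None))
        raise ConfigError(f"unknown shape kind {self.kind!r}")


def _gamma_pulse(t: np.ndarray, tau: float, k: float) -> np.ndarray:
    """Unimodal kernel with unit peak at t = τ, zero for t ≤ 0."""
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    x = t[pos] / tau
    out[pos] = x**k * np.exp(k * (1.0 - x))
    return out


#: canonical response shapes per (test, epoch, modality)
SHAPES: dict[tuple[str, str, str], ShapeSpec] = {
    # squat: pressor/baroreflex transients at each posture change
    ("squat", "squat", "HR"): ShapeSpec("gamma", 0.12, tau=10, k=2),
    ("squat", "squat", "MAP"): ShapeSpec("gamma", 0.18, tau=15, k=2),
    ("squat", "squat", "RMSSD"): ShapeSpec("gamma", -0.15, tau=20, k=2),
    ("squat", "stand", "HR"): ShapeSpec("gamma", 0.20, tau=8, k=2),
    ("squat", "stand", "MAP"): ShapeSpec("bigamma", -0.15, tau=6, k=2,
                                          amp2=0.08, tau2=25, k2=2),
    ("squat", "stand", "RMSSD"): ShapeSpec("gamma", -0.20, tau=15, k=2),
    # cold pressor: sustained pressor response
    ("cold_pressor", "hand_in", "MAP"): ShapeSpec("plateau", 0.20, tau=20),
    ("cold_pressor", "hand_out", "MAP"): ShapeSpec("gamma", -0.12, tau=15, k=2),
    # diving reflex: bradycardia with pressor component
    ("diving_reflex", "mask_on", "HR"): ShapeSpec("gamma", -0.15, tau=15, k=2),
    ("diving_reflex", "mask_on", "MAP"): ShapeSpec("gamma", 0.15, tau=20, k=2),
    ("diving_reflex", "mask_on", "RMSSD"): ShapeSpec("gamma", 0.25, tau=25, k=2),
    ("diving_reflex", "mask_off", "HR"): ShapeSpec("gamma", 0.08, tau=10, k=2),
    ("diving_reflex", "mask_off", "MAP"): ShapeSpec("gamma", -0.08, tau=12, k=2),
    # Valsalva: four-phase hemodynamics
    ("valsalva", "inhale", "MAP"): ShapeSpec("gamma", 0.08, tau=2, k=2),
    ("valsalva", "vm", "MAP"): ShapeSpec("bigamma", 0.15, tau=3, k=2,
                                          amp2=-0.12, tau2=10, k2=3),
    ("valsalva", "vm", "HR"): ShapeSpec("gamma", 0.20, tau=10, k=2),
    ("valsalva", "release", "MAP"): ShapeSpec("gamma", 0.15, tau=4, k=2),
    ("valsalva", "release", "HR"): ShapeSpec("gamma", -0.15, tau=5, k=2),
    # deep breathing: paced respiratory sinus arrhythmia; RMSSD elevation
    ("deep_breathing", "first_2min", "HR"): ShapeSpec("sine", 0.08, freq=0.1),
    ("deep_breathing", "first_2min", "RMSSD"): ShapeSpec("plateau", 0.30, tau=20),
}


def _epoch_for(test: str, epoch: str) -> Epoch:
    for ep in get_test(test).epochs:
        if ep.name == epoch:
            return ep
    raise ConfigError(f"test {test!r} has no epoch {epoch!r}")


def make_template_shape(test: str, epoch: str, modality: str,
                        fs: float = EPOCH_FS) -> np.ndarray:
    """Canonical response curve on the epoch grid."""
    try:
        spec = SHAPES[(test, epoch, modality)]
    except KeyError:
        raise ConfigError(
            f"no canonical shape for {(test, epoch, modality)}"
        ) from None
    grid = _epoch_for(test, epoch).grid(fs)
    return spec.evaluate(grid)


def canonical_template(test: str, epoch: str, modality: str,
                       fs: float = EPOCH_FS) -> Template:
    """Canonical shape wrapped as a gated-in Template (synthetic truth)."""
    grid = _epoch_for(test, epoch).grid(fs)
    f = make_template_shape(test, epoch, modality, fs)
    return Template(t=grid, f=f, x0=0.0, n_traces=1, sig=True,
                    test=test, epoch=epoch, modality=modality,
                    meta={"synthetic": True})


def canonical_template_keys(template_matched_only: bool = True):
    """Keys of the canonical shapes; template matching excludes the paced
    deep-breathing HR oscillation (its feature is the cycle peak-to-peak
    excursion, not a template fit)."""
    keys = list(SHAPES)
    if template_matched_only:
        keys.remove(("deep_breathing", "first_2min", "HR"))
    return keys


@dataclass
class GroundTruth:
    """Injected parameters for a simulated cohort or session.

    ``cells`` maps (subject, session, test, epoch, modality) to a dict with
    duration (multiplier, > 0), delay (s, template-time), amplitude and
    offset. ``subjects`` maps subject id to covariates.
    """

    seed: int
    subjects: dict = field(default_factory=dict)
    cells: dict = field(default_factory=dict)
    noise_sigma: float = 0.0
    params: dict = field(default_factory=dict)

    def cell(self, subject, session, test, epoch, modality) -> dict:
        return self.cells[(subject, session, test, epoch, modality)]


def simulate_response(
    shape,
    *,
    duration: float = 1.0,
    delay: float = 0.0,
    amplitude: float = 1.0,
    offset: float = 0.0,
    noise_sigma: float = 0.0,
    rng=None,
    **meta,
) -> ResponseTrace:
    """Apply the template transform with known truth plus white noise.

    ``shape`` is a Template (or a (test, epoch, modality) key). The
    transform is y(τ) = amplitude·f(τ/duration − delay) + offset + ε, i.e.
    the fitted model with a = 1/duration, b = delay, c = amplitude,
    d = offset; ε ~ N(0, noise_sigma²) i.i.d. on the grid.
    """
    if duration <= 0:
        raise DataError("duration multiplier must be positive")
    if isinstance(shape, tuple):
        shape = canonical_template(*shape)
    from .matching import transform_template  # local: avoid import cycle

    a = 1.0 / duration
    y = transform_template(shape, a, delay, amplitude, offset)
    if noise_sigma > 0:
        rng = np.random.default_rng(rng)
        y = y + rng.normal(0.0, noise_sigma, size=y.shape)
    meta.setdefault("test", shape.test)
    meta.setdefault("epoch", shape.epoch)
    meta.setdefault("modality", shape.modality)
    return ResponseTrace(t=shape.t.copy(), y=y, **meta)


def _sympathetic_cells():
    return {(r.test, r.epoch, r.modality) for r in DEFAULT_RULES
            if r.branch == "S"}


def simulate_cohort(
    n_subjects: int = 21,
    sessions_per_subject: int = 4,
    cells=None,
    *,
    beta: float = 0.05,
    alpha: float | None = None,
    bmi_mean: float = 24.4,
    bmi_sd: float = 2.9,
    age_mean: float = 29.9,
    age_sd: float = 6.5,
    subject_amp_sd: float = 0.12,
    session_amp_sd: float = 0.10,
    duration_log_sd: float = 0.15,
    delay_sd: float = 1.0,
    offset_sd: float = 0.02,
    noise_sigma: float | None = None,
    noise_scale: float = 0.1,
    ampm_amp_gain: dict | None = None,
    ampm_dur_gain: dict | None = None,
    seed: int = 0,
):
    """Simulate a cohort of baseline-normalized response traces with truth.

    Cohort demographics follow the healthy-adult study population (n = 21,
    BMI 24.4 ± 2.9 kg/m², age 29.9 ± 6.5 y, 16 male / 5 female, four
    sessions each: two AM, two PM). The amplitude of sympathetically
    classified cells follows α + β·BMI + ε with between-subject SD
    ``subject_amp_sd`` and between-session SD ``session_amp_sd``;
    parasympathetic/unclassified cells are centred on 1 with the same
    variability. Optional AM/PM gain multipliers ({'AM': g, 'PM': g} per
    branch, e.g. {'PM': {'S': 1.3}}) emulate circadian modulation.

    Trace noise is white Gaussian with per-cell σ = ``noise_scale`` × the
    canonical template's peak magnitude (the same convention the
    robustness simulations use), unless an absolute ``noise_sigma``
    overrides it for all cells.

    Returns (traces, truth) where traces is a flat list of ResponseTrace
    with subject/session metadata and truth records every injected value.
    """
    rng = np.random.default_rng(seed)
    if cells is None:
        cells = canonical_template_keys()
    if alpha is None:
        alpha = 1.0 - beta * bmi_mean  # mean amplitude 1 at the cohort-mean BMI
    symp = _sympathetic_cells()
    templates = {key: canonical_template(*key) for key in cells}
    sigma_by_cell = {
        key: (noise_sigma if noise_sigma is not None
              else noise_scale * float(np.max(np.abs(templates[key].f))))
        for key in cells
    }
    truth = GroundTruth(
        seed=seed,
        noise_sigma=float(np.sqrt(np.mean(np.square(list(sigma_by_cell.values()))))),
        params=dict(beta=beta, alpha=alpha, subject_amp_sd=subject_amp_sd,
                    session_amp_sd=session_amp_sd,
                    duration_log_sd=duration_log_sd, delay_sd=delay_sd,
                    offset_sd=offset_sd, noise_scale=noise_scale,
                    noise_sigma_by_cell={"/".join(k): v
                                         for k, v in sigma_by_cell.items()}),
    )
    traces = []
    n_male = round(n_subjects * 16 / 21)
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        bmi = float(np.clip(rng.normal(bmi_mean, bmi_sd), 18.5, 29.9))
        age = float(np.clip(rng.normal(age_mean, age_sd), 18, 60))
        sex = "M" if i < n_male else "F"
        amp_s_subject = alpha + beta * bmi + rng.normal(0.0, subject_amp_sd)
        amp_p_subject = 1.0 + rng.normal(0.0, subject_amp_sd)
        dur_subject = float(np.exp(rng.normal(0.0, duration_log_sd)))
        truth.subjects[sid] = dict(bmi=bmi, age=age, sex=sex,
                                   amp_sympathetic=amp_s_subject,
                                   amp_other=amp_p_subject,
                                   duration=dur_subject)
        for sess in range(1, sessions_per_subject + 1):
            tod = "AM" if sess <= sessions_per_subject // 2 else "PM"
            for key in cells:
                base = amp_s_subject if key in symp else amp_p_subject
                branch = "S" if key in symp else "P"
                amp = base + rng.normal(0.0, session_amp_sd)
                dur = dur_subject * float(np.exp(rng.normal(0.0, duration_log_sd / 2)))
                if ampm_amp_gain and tod in ampm_amp_gain:
                    amp *= ampm_amp_gain[tod].get(branch, 1.0)
                if ampm_dur_gain and tod in ampm_dur_gain:
                    dur *= ampm_dur_gain[tod].get(branch, 1.0)
                amp = max(amp, 0.1)
                dur = float(np.clip(dur, 0.5, 2.0))
                epoch_len = templates[key].t[-1] - templates[key].t[0]
                delay = float(np.clip(rng.normal(0.0, delay_sd),
                                      -0.1 * epoch_len, 0.1 * epoch_len))
                off = float(rng.normal(0.0, offset_sd))
                params = dict(duration=dur, delay=delay, amplitude=float(amp),
                              offset=off)
                truth.cells[(sid, sess, *key)] = params
                traces.append(simulate_response(
                    templates[key], noise_sigma=sigma_by_cell[key], rng=rng,
                    subject=sid, session=sess, time_of_day=tod, **params,
                ))
    return traces, truth


# ---------------------------------------------------------------------------
# raw 1 kHz session synthesis


def make_session_manifest(
    subject_id: str = "S01",
    session_index: int = 1,
    time_of_day: str = "AM",
    bmi: float = 24.4,
    age: float = 29.9,
    sex: str = "M",
    tests=None,
    baseline_s: float = 130.0,
    db_duration: float = 420.0,
    fs: float = 1000.0,
) -> SessionManifest:
    """Lay out a session timeline: a sitting baseline before each test.

    The default 130 s inter-test rest leaves room for the 60 s RMSSD
    sliding window plus a full 60 s baseline window (ending 5 s before
    the test) even for the first test of the session.
    """
    if tests is None:
        tests = list(TEST_DEFINITIONS)
    events = []
    t = baseline_s
    for test in tests:
        td = get_test(test)
        for phase, dur in td.phases:
            if test == "deep_breathing" and phase == "breathe":
                dur = db_duration
            events.append((test, phase, t))
            t += dur
        t += baseline_s  # next test's pre-test sitting baseline
    return SessionManifest(
        subject_id=subject_id, session_index=session_index,
        time_of_day=time_of_day, bmi=bmi, age=age, sex=sex,
        events=events, fs=fs,
    )


def _response_curve(manifest, cell_truth, modality, t):
    """Summed warped responses of one modality on the session time axis.

    Each cell contributes amplitude·f(τ/duration − delay) inside its epoch
    window, linearly tapered to zero over 20 s past the window so the raw
    signal has no step discontinuities.
    """
    y = np.zeros_like(t)
    for (test, epoch, mod), p in cell_truth.items():
        if mod != modality:
            continue
        spec = SHAPES.get((test, epoch, mod))
        if spec is None:
            raise ConfigError(f"no shape for cell {(test, epoch, mod)}")
        ep = _epoch_for(test, epoch)
        anchor = manifest.phase_time(test, ep.anchor_phase)
        taper = 20.0
        sel = (t >= anchor + ep.start) & (t <= anchor + ep.end + taper)
        tau = t[sel] - anchor
        val = p["amplitude"] * spec.evaluate(tau / p["duration"] - p["delay"]) \
            + p.get("offset", 0.0)
        w = np.ones_like(tau)
        over = tau > ep.end
        w[over] = np.clip(1.0 - (tau[over] - ep.end) / taper, 0.0, 1.0)
        y[sel] += val * w
    return y


def simulate_raw_session(
    cell_truth: dict,
    manifest: SessionManifest | None = None,
    *,
    hr0: float = 60.0,
    map0: float = 90.0,
    pulse_amp: float = 20.0,
    rsa_amp: float = 0.08,
    base_rmssd_ms: float = 0.0,
    line_noise_mv: float = 0.0,
    pupil_slope: float = -1.5,
    pupil_base: float = 5.0,
    seed: int = 0,
) -> Recording:
    """Synthesize a full 1 kHz multichannel session from cell-level truth.

    ``cell_truth`` maps (test, epoch, modality) to dicts with duration,
    delay, amplitude, offset (the same parameterization the fitter
    recovers). The heart-rate curve drives an impulse-train ECG (Gaussian R
    spike + T bump); the blood-pressure channel is a per-beat pulse whose
    beat average equals the target MAP exactly; respiration is paced at
    6/min during deep breathing and 15/min otherwise; deep-breathing
    respiratory sinus arrhythmia has fractional amplitude ``rsa_amp`` scaled
    by the deep-breathing cell amplitude. ``base_rmssd_ms`` > 0 adds
    beat-to-beat Gaussian jitter whose RMSSD tracks any RMSSD cells.
    ``line_noise_mv`` adds 60 Hz contamination to ECG and BP.
    """
    rng = np.random.default_rng(seed)
    if manifest is None:
        tests = sorted({test for (test, _, _) in cell_truth})
        order = [tn for tn in TEST_DEFINITIONS if tn in tests]
        manifest = make_session_manifest(tests=order)
    fs = manifest.fs
    last_event = max(t for _, _, t in manifest.events)
    last_test, last_phase, _ = max(manifest.events, key=lambda e: e[2])
    tail = dict(get_test(last_test).phases).get(last_phase, 60.0) + 40.0
    n = int(round((last_event + tail) * fs))
    t = np.arange(n) / fs

    hr_curve = hr0 * (1.0 + _response_curve(manifest, cell_truth, "HR", t))
    # paced-breathing sinus arrhythmia during the deep-breathing phase
    db_amp = None
    for (test, epoch, mod), p in cell_truth.items():
        if test == "deep_breathing" and mod == "HR":
            db_amp = p["amplitude"]
    if db_amp is not None and "deep_breathing" in manifest.tests_present():
        t_db = manifest.phase_time("deep_breathing", "breathe")
        dur_db = [d for ph, d in get_test("deep_breathing").phases][0]
        for tst, ph, tt in manifest.events:
            if tst == "deep_breathing" and ph == "breathe":
                t_db = tt
        sel = (t >= t_db)
        # breathe until the next event or end of recording
        later = [tt for _, _, tt in manifest.events if tt > t_db]
        t_end_db = min(later) if later else t[-1]
        sel &= t < t_end_db
        hr_curve[sel] *= 1.0 + rsa_amp * db_amp * np.sin(
            2 * np.pi * 0.1 * (t[sel] - t_db))

    map_curve = map0 * (1.0 + _response_curve(manifest, cell_truth, "MAP", t))
    rmssd_curve = _response_curve(manifest, cell_truth, "RMSSD", t)

    # beat times by integrating the instantaneous rate
    beats = [0.35]  # first beat shortly after recording start
    while beats[-1] < t[-1] - 2.0:
        h = float(np.interp(beats[-1], t, hr_curve))
        ibi = 60.0 / max(h, 20.0)
        if base_rmssd_ms > 0:
            local = 1.0 + float(np.interp(beats[-1], t, rmssd_curve))
            ibi += rng.normal(0.0, base_rmssd_ms * max(local, 0.0) / np.sqrt(2)) / 1000.0
        beats.append(beats[-1] + max(ibi, 0.25))
    beats = np.asarray(beats)

    # ECG: Gaussian R spike (1 mV, sigma 8 ms) + T bump (0.15 mV at +200 ms)
    ecg = np.zeros(n)
    for tb in beats:
        for amp, off, sig in ((1.0, 0.0, 0.008), (0.15, 0.200, 0.030)):
            i0 = int((tb + off - 4 * sig) * fs)
            i1 = int((tb + off + 4 * sig) * fs)
            if i1 <= 0 or i0 >= n:
                continue
            i0, i1 = max(i0, 0), min(i1, n)
            tt = t[i0:i1] - (tb + off)
            ecg[i0:i1] += amp * np.exp(-0.5 * (tt / sig) ** 2)

    # BP: per-beat pulse with beat-mean exactly on the MAP curve
    bp = np.full(n, map0)
    for s, e in zip(beats[:-1], beats[1:]):
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 - i0 < 2:
            continue
        m = float(np.interp(0.5 * (s + e), t, map_curve))
        phase = np.arange(i1 - i0) / (i1 - i0)
        bp[i0:i1] = m + pulse_amp * np.sin(2 * np.pi * phase)

    # respiration: 6 breaths/min while paced, 15/min otherwise
    f_resp = np.full(n, 0.25)
    if "deep_breathing" in manifest.tests_present():
        t_db = manifest.phase_time("deep_breathing", "breathe")
        later = [tt for _, _, tt in manifest.events if tt > t_db]
        t_end_db = min(later) if later else t[-1]
        f_resp[(t >= t_db) & (t < t_end_db)] = 0.1
    resp = np.sin(2 * np.pi * np.cumsum(f_resp) / fs)

    eda = 2.0 + 0.1 * np.sin(2 * np.pi * t / 300.0)

    # gaze luminance wanders slowly; pupil responds linearly to it
    lum = 0.5 + 0.3 * np.sin(2 * np.pi * t / 97.0) + 0.15 * np.sin(2 * np.pi * t / 41.0)
    lum = np.clip(lum, 0.0, 1.0)
    gaze = np.clip(np.round(255.0 * lum), 0, 255)
    gaze_rgb = np.column_stack([gaze, gaze, gaze])
    pupil = pupil_base + pupil_slope * lum

    if line_noise_mv > 0:
        mains = np.sin(2 * np.pi * 60.0 * t)
        ecg = ecg + line_noise_mv * mains
        bp = bp + 10 * line_noise_mv * mains

    return Recording(
        channels={"ECG": ecg, "BP": bp, "RESP": resp, "EDA": eda,
                  "PUPIL": pupil, "GAZE": gaze_rgb},
        fs=fs,
        units={"ECG": "mV", "BP": "mmHg", "RESP": "a.u.", "EDA": "uS",
               "PUPIL": "mm", "GAZE": "rgb"},
    )
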