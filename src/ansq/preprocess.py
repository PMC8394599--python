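"""Derive physiological response signals from raw channels.

Raw 1 kHz channels (ECG, continuous finger blood pressure, respiration,
electrodermal activity, pupil diameter + gaze RGB) become uniformly sampled
derived signals:

* HR (bpm) — instantaneous heart rate from detected R peaks;
* RMSSD (ms) — root mean square of successive inter-beat-interval
  differences in a sliding 60 s window (short-term HRV, parasympathetic
  proxy; only meaningful for tests spanning more than 60 s);
* MAP (mmHg) — per-beat time average of the arterial pressure waveform;
* EDA (µS) — low-passed electrodermal activity;
* PUPIL — pupil diameter normalized for gaze-point luminance.

All cardiovascular channels pass a zero-phase 60 Hz notch first so that
line noise never reaches beat detection or averaging, and zero-phase
filtering leaves event latencies undistorted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, SignalQualityError, DataError

__all__ = [
    "BeatSeries",
    "DerivedSignal",
    "notch_filter",
    "detect_r_peaks",
    "reject_ibi_artifacts",
    "compute_heart_rate",
    "compute_rmssd_series",
    "compute_map_series",
    "normalize_pupil",
    "smooth_eda",
    "relative_luminance",
]

#: default uniform output rate for derived signals, Hz
DERIVED_FS = 4.0

#: physiologic inter-beat-interval bounds, ms (20–240 bpm)
IBI_BOUNDS_MS = (250.0, 3000.0)


@dataclass
class BeatSeries:
    """R-peak times (s) and the successive inter-beat intervals (ms)."""

    r_peak_times: np.ndarray

    def __post_init__(self) -> None:
        self.r_peak_times = np.asarray(self.r_peak_times, dtype=float)
        if self.r_peak_times.size >= 2 and np.any(np.diff(self.r_peak_times) <= 0):
            raise DataError("R-peak times must be strictly increasing")

    @property
    def ibi(self) -> np.ndarray:
        """Successive inter-beat intervals in ms, ibi[i] = 1000·(t[i+1] − t[i])."""
        return 1000.0 * np.diff(self.r_peak_times)

    @property
    def n_beats(self) -> int:
        return int(self.r_peak_times.size)


@dataclass
class DerivedSignal:
    """Uniformly resampled derived physiological series."""

    name: str
    t: np.ndarray
    v: np.ndarray
    fs_out: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape:
            raise DataError("t and v must share a shape")


def notch_filter(x, fs: float, f0: float = 60.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at ``f0`` (≥ 30 dB rejection, flat passband).

    Applied forward–backward (filtfilt) so event latencies are preserved.
    """
    if fs <= 2 * f0:
        raise ConfigError(
            f"sampling rate {fs} Hz too low to notch {f0} Hz (need > {2 * f0})"
        )
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    b, a = sps.iirnotch(f0, q, fs=fs)
    return sps.filtfilt(b, a, x)


def detect_r_peaks(ecg, fs: float, refractory_s: float = 0.25) -> BeatSeries:
    """Detect R waves: band-pass, squared derivative, adaptive threshold.

    A Pan–Tompkins-style energy detector: 5–25 Hz band-pass isolates the QRS
    complex, the squared derivative emphasizes its steep slopes, a 150 ms
    moving integration smooths to one hump per beat, and peaks are picked
    with a 250 ms refractory period above an adaptive (percentile-based)
    threshold. Peak times are refined to the absolute maximum of the
    band-passed ECG near each energy peak.
    """
    if fs < 250:
        raise ConfigError("R-peak detection requires fs >= 250 Hz")
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < int(fs):
        raise SignalQualityError("ECG shorter than 1 s")
    sos = sps.butter(2, [5.0, 25.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, ecg)
    energy = np.gradient(bp) ** 2
    win = max(3, int(round(0.150 * fs)))
    kernel = np.ones(win) / win
    env = np.convolve(energy, kernel, mode="same")
    scale = np.percentile(env, 99)
    if scale <= 0 or not np.isfinite(scale):
        raise SignalQualityError("flat or invalid ECG: no QRS energy")
    idx, _ = sps.find_peaks(env, height=0.2 * scale,
                            distance=int(round(refractory_s * fs)))
    if idx.size < 2:
        raise SignalQualityError("fewer than 2 R peaks detected")
    # refine to local extremum of |band-passed ECG|
    half = int(round(0.05 * fs))
    times = []
    for i in idx:
        lo, hi = max(0, i - half), min(ecg.size, i + half + 1)
        j = lo + int(np.argmax(np.abs(bp[lo:hi])))
        times.append(j / fs)
    times = np.unique(np.asarray(times))
    # enforce refractory after refinement
    keep = [0]
    for k in range(1, times.size):
        if times[k] - times[keep[-1]] >= refractory_s:
            keep.append(k)
    times = times[keep]
    # signal-quality check: at least 2 peaks in any 10 s span
    span = ecg.size / fs
    if span >= 10.0:
        edges = np.arange(0.0, span - 10.0 + 1e-9, 5.0)
        for s in edges:
            if np.sum((times >= s) & (times < s + 10.0)) < 2:
                raise SignalQualityError(
                    f"fewer than 2 beats in 10 s window at t={s:.0f}s"
                )
    return BeatSeries(times)


def reject_ibi_artifacts(beats: BeatSeries, max_rel_dev: float = 0.30):
    """Drop ectopic/artifact intervals before HRV analysis.

    An interval is rejected when outside the 250–3000 ms physiologic bounds
    or deviating more than 30% from the running (11-beat) median. Returns
    (pair start times, cleaned ibi array in ms); the pairing with beat
    times is preserved for windowed statistics.
    """
    ibi = beats.ibi
    if ibi.size == 0:
        return np.array([]), np.array([])
    lo, hi = IBI_BOUNDS_MS
    n = ibi.size
    med = np.empty(n)
    half = 5
    for i in range(n):
        s, e = max(0, i - half), min(n, i + half + 1)
        med[i] = np.median(ibi[s:e])
    ok = (ibi >= lo) & (ibi <= hi) & (np.abs(ibi - med) <= max_rel_dev * med)
    return beats.r_peak_times[:-1][ok], ibi[ok]


def compute_heart_rate(beats: BeatSeries, fs_out: float = DERIVED_FS) -> DerivedSignal:
    """Instantaneous HR = 60000/ibi at beat times, interpolated to a grid."""
    if beats.n_beats < 2:
        raise DataError("need at least 2 beats for heart rate")
    ibi = beats.ibi
    hr = 60000.0 / ibi
    t_beat = beats.r_peak_times[1:]  # assigned at the closing beat of each interval
    t0, t1 = beats.r_peak_times[0], beats.r_peak_times[-1]
    grid = np.arange(np.ceil(t0 * fs_out), np.floor(t1 * fs_out) + 1) / fs_out
    v = np.interp(grid, t_beat, hr)
    return DerivedSignal("HR", grid, v, fs_out)


def compute_rmssd_series(
    beats: BeatSeries,
    window_s: float = 60.0,
    step_s: float = 1.0,
    min_intervals: int = 3,
) -> DerivedSignal:
    """Sliding-window RMSSD (ms) over artifact-cleaned inter-beat intervals.

    At each grid time t the RMSSD is computed over successive-interval
    differences whose beats fall within [t − window_s, t]. Windows with
    fewer than ``min_intervals`` intervals are undefined (NaN gap). RMSSD
    needs a full 60 s of beats to be accurate, so it is only meaningful for
    the longer tests (squat, deep breathing, diving reflex).
    """
    t_pair, ibi = reject_ibi_artifacts(beats)
    span = beats.r_peak_times[-1] - beats.r_peak_times[0]
    if span < window_s:
        raise DataError(
            f"recording span {span:.1f} s shorter than RMSSD window {window_s} s"
        )
    t0 = beats.r_peak_times[0]
    grid = np.arange(t0 + window_s, beats.r_peak_times[-1] + 1e-9, step_s)
    out = np.full(grid.shape, np.nan)
    # interval i covers beats at t_pair[i] .. t_pair[i] + ibi[i]
    t_close = t_pair + ibi / 1000.0
    for k, t in enumerate(grid):
        sel = (t_pair >= t - window_s) & (t_close <= t)
        if sel.sum() < min_intervals:
            continue
        d = np.diff(ibi[sel])
        # successive differences only where the intervals are adjacent
        adj = np.isclose(t_close[sel][:-1], t_pair[sel][1:], atol=1e-6)
        d = d[adj]
        if d.size < min_intervals - 1:
            continue
        out[k] = np.sqrt(np.mean(d**2))
    fs_out = 1.0 / step_s
    return DerivedSignal("RMSSD", grid, out, fs_out)


def compute_map_series(
    bp,
    fs: float,
    beats: BeatSeries,
    fs_out: float = DERIVED_FS,
) -> DerivedSignal:
    """Per-beat mean arterial pressure interpolated to a uniform grid.

    MAP is the time average of the continuous pressure waveform over each
    beat interval — the definition of mean arterial pressure when the full
    waveform is available from the finger cuff.
    """
    bp = np.asarray(bp, dtype=float)
    if beats.n_beats < 2:
        raise DataError("need at least 2 beats for MAP")
    tb = beats.r_peak_times
    means = []
    mids = []
    for s, e in zip(tb[:-1], tb[1:]):
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        i0, i1 = max(0, i0), min(bp.size, i1)
        if i1 - i0 < 2:
            continue
        means.append(float(np.mean(bp[i0:i1])))
        mids.append(0.5 * (s + e))
    if len(means) < 2:
        raise DataError("too few beats overlap the BP waveform")
    means = np.asarray(means)
    mids = np.asarray(mids)
    bad = (means < 20.0) | (means > 300.0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} beats with non-physiologic MAP "
            "(< 20 or > 300 mmHg) flagged", stacklevel=2,
        )
    grid = np.arange(np.ceil(mids[0] * fs_out), np.floor(mids[-1] * fs_out) + 1) / fs_out
    v = np.interp(grid, mids, means)
    return DerivedSignal("MAP", grid, v, fs_out)


#: relative-luminance coefficients of the photopic luminosity function
LUMA_COEFFS = (0.2126, 0.7152, 0.0722)


def relative_luminance(rgb) -> np.ndarray:
    """L = 0.2126 R + 0.7152 G + 0.0722 B with RGB scaled to [0, 1]."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim == 1:
        rgb = rgb[None, :]
    if rgb.shape[-1] != 3:
        raise DataError("gaze RGB must have 3 components")
    scaled = rgb / 255.0
    r, g, b = scaled[..., 0], scaled[..., 1], scaled[..., 2]
    return LUMA_COEFFS[0] * r + LUMA_COEFFS[1] * g + LUMA_COEFFS[2] * b


def normalize_pupil(
    pupil,
    gaze_rgb,
    t=None,
    fs: float | None = None,
    slope_floor: float = 1e-6,
) -> DerivedSignal:
    """Normalize pupil diameter for gaze-point luminance.

    The RGB of the gaze location is converted to relative luminance L, L is
    linearly fit to pupil diameter (OLS, pupil = s·L + k), and the pupil
    series is divided by the slope s, removing the luminance-driven
    component's scale so autonomic changes dominate. If luminance is
    (near-)constant or the fitted |slope| is below ``slope_floor`` the
    series is passed through unmodified with a warning.
    """
    pupil = np.asarray(pupil, dtype=float)
    L = relative_luminance(gaze_rgb)
    if L.shape != pupil.shape:
        raise DataError("pupil and gaze streams must be time-aligned")
    if t is None:
        if fs is None:
            fs = 1.0
        t = np.arange(pupil.size) / fs
    else:
        t = np.asarray(t, dtype=float)
        fs = fs or (1.0 / float(np.median(np.diff(t))) if t.size > 1 else 1.0)
    if float(np.ptp(L)) == 0.0:
        warnings.warn(
            "constant gaze luminance: pupil passed through unnormalized",
            stacklevel=2,
        )
        return DerivedSignal("PUPIL", t, pupil.copy(), fs)
    slope, _intercept = np.polyfit(L, pupil, 1)
    if abs(slope) < slope_floor:
        warnings.warn(
            f"luminance fit slope {slope:.2g} below floor {slope_floor}: "
            "pupil passed through unnormalized", stacklevel=2,
        )
        return DerivedSignal("PUPIL", t, pupil.copy(), fs)
    return DerivedSignal("PUPIL", t, pupil / slope, fs)


def smooth_eda(eda, fs: float, cutoff: float = 1.0,
               fs_out: float = DERIVED_FS) -> DerivedSignal:
    """Low-pass EDA at 1 Hz and decimate to the derived-signal grid.

    EDA enters the pipeline solely to be evaluated by the significance
    gate; in the healthy cohort it fails the gate and is excluded from
    feature extraction.
    """
    eda = np.asarray(eda, dtype=float)
    if fs <= 2 * cutoff:
        raise ConfigError("EDA sampling rate too low for the 1 Hz low-pass")
    sos = sps.butter(4, cutoff, btype="low", fs=fs, output="sos")
    v = sps.sosfiltfilt(sos, eda)
    t = np.arange(eda.size) / fs
    grid = np.arange(0.0, t[-1] + 1e-9, 1.0 / fs_out)
    return DerivedSignal("EDA", grid, np.interp(grid, t, v), fs_out)
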