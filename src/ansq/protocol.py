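"""Autonomic test protocol: the five standard tests, their phases and epochs.

Each session contains five clinical autonomic tests in randomized order:

* **squat** — stand 1 min, deep squat 1 min, stand 1 min (posture stressor,
  sympathetic pressor / baroreflex response at each transition);
* **cold_pressor** — hand in ice water for at least 30 s and up to 3 min
  (sympathetic pressor response);
* **deep_breathing** — paced breathing at 6 breaths/min for 7 min
  (parasympathetic respiratory sinus arrhythmia; only the first 2 min are
  analyzed);
* **diving_reflex** — refrigerated compress on the face for 1 min followed by
  recovery (parasympathetically mediated bradycardia);
* **valsalva** — forced expiration against a closed airway for 15 s with a
  minute of recovery (four hemodynamic epochs).

An *epoch* is an analysis window anchored at a protocol event (a posture
change, hand immersion, mask placement, or a Valsalva phase boundary).
Derived signals are cut to these windows and normalized by a baseline taken
in sitting posture before each test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError, ProtocolError

#: grid rate for response traces and templates, Hz
EPOCH_FS = 4.0


@dataclass(frozen=True)
class Epoch:
    """Analysis window anchored at a phase-start event.

    ``start``/``end`` are seconds relative to the anchor event; the anchor
    itself is time 0 of the epoch grid (the ``x0`` of the template
    transform).
    """

    name: str
    anchor_phase: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ConfigError(f"epoch {self.name!r}: window must have positive length")

    @property
    def length(self) -> float:
        return self.end - self.start

    def grid(self, fs: float = EPOCH_FS) -> np.ndarray:
        """Uniform time grid (s, relative to the anchor) for this epoch."""
        n = int(round((self.end - self.start) * fs)) + 1
        return self.start + np.arange(n) / fs


@dataclass(frozen=True)
class TestDefinition:
    name: str
    phases: tuple[tuple[str, float], ...]  # (phase name, nominal duration s)
    epochs: tuple[Epoch, ...]

    @property
    def phase_names(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.phases)

    @property
    def nominal_duration(self) -> float:
        return float(sum(d for _, d in self.phases))


TEST_DEFINITIONS: dict[str, TestDefinition] = {
    "squat": TestDefinition(
        "squat",
        phases=(("stand_pre", 60.0), ("squat", 60.0), ("stand", 60.0)),
        epochs=(
            Epoch("squat", "squat", 0.0, 60.0),
            Epoch("stand", "stand", 0.0, 60.0),
        ),
    ),
    "cold_pressor": TestDefinition(
        "cold_pressor",
        phases=(("hand_in", 60.0), ("hand_out", 60.0)),
        epochs=(
            Epoch("hand_in", "hand_in", 0.0, 60.0),
            Epoch("hand_out", "hand_out", 0.0, 60.0),
        ),
    ),
    "deep_breathing": TestDefinition(
        "deep_breathing",
        # paced at 6 breaths/min; only the first two minutes are analyzed
        phases=(("breathe", 420.0),),
        epochs=(Epoch("first_2min", "breathe", 0.0, 120.0),),
    ),
    "diving_reflex": TestDefinition(
        "diving_reflex",
        phases=(("mask_on", 60.0), ("mask_off", 60.0)),
        epochs=(
            Epoch("mask_on", "mask_on", 0.0, 60.0),
            Epoch("mask_off", "mask_off", 0.0, 60.0),
        ),
    ),
    "valsalva": TestDefinition(
        "valsalva",
        phases=(
            ("inhale", 5.0),
            ("vm", 15.0),
            ("release", 10.0),
            ("recovery", 60.0),
        ),
        epochs=(
            Epoch("inhale", "inhale", 0.0, 5.0),
            Epoch("vm", "vm", 0.0, 15.0),
            Epoch("release", "release", 0.0, 10.0),
            Epoch("recovery", "recovery", 0.0, 60.0),
        ),
    ),
}

TEST_NAMES = tuple(TEST_DEFINITIONS)

#: tests long enough for a 60 s RMSSD window (RMSSD is not computed for the
#: cold pressor test or the Valsalva maneuver)
RMSSD_TESTS = ("squat", "deep_breathing", "diving_reflex")


def get_test(name: str) -> TestDefinition:
    try:
        return TEST_DEFINITIONS[name]
    except KeyError:
        raise ConfigError(f"unknown autonomic test {name!r}") from None


def define_epochs(test: TestDefinition | str) -> tuple[Epoch, ...]:
    """Return the analysis epochs of a test (e.g. 4 for the Valsalva)."""
    if isinstance(test, str):
        test = get_test(test)
    return test.epochs


@dataclass(frozen=True)
class BaselineStats:
    """Baseline mean/SD over a pre-test sitting window of a derived signal."""

    mu: float
    sigma: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise DataError("baseline sigma must be >= 0")

    @property
    def sigma_normalized(self) -> float:
        """Baseline SD in baseline-normalized (fractional-change) units."""
        if self.mu == 0:
            return float("inf")
        return self.sigma / abs(self.mu)


@dataclass
class ResponseTrace:
    """Baseline-normalized response of one individual in one epoch.

    ``t`` is seconds relative to the epoch anchor; ``y`` is the fractional
    change from the baseline mean (dimensionless). ``extrapolated`` marks
    samples filled by holding the last observed value (e.g. early hand
    removal in the cold pressor test); template averaging excludes them and
    fitting restricts the objective to the observed samples.
    """

    t: np.ndarray
    y: np.ndarray
    modality: str
    test: str
    epoch: str
    subject: str = ""
    session: int = 0
    time_of_day: str = ""
    extrapolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.extrapolated is None:
            self.extrapolated = np.zeros(self.t.shape, dtype=bool)
        else:
            self.extrapolated = np.asarray(self.extrapolated, dtype=bool)
        if not (self.t.shape == self.y.shape == self.extrapolated.shape):
            raise DataError("ResponseTrace arrays must share one shape")

    @property
    def observed(self) -> np.ndarray:
        return ~self.extrapolated


def _test_event_times(events, test_name: str) -> list[tuple[str, float]]:
    return [(ph, t) for (tst, ph, t) in events if tst == test_name]


def baseline_stats(
    signal,
    manifest,
    test: str,
    window_s: float = 60.0,
    gap_s: float = 5.0,
    min_s: float = 30.0,
) -> BaselineStats:
    """Baseline mean and SD over a sitting window preceding ``test``.

    The window is ``window_s`` long and ends ``gap_s`` before the test's
    first protocol event, shrunk (down to ``min_s``) if the recording or a
    preceding test leaves less room.
    """
    evs = _test_event_times(manifest.events, test)
    if not evs:
        raise ProtocolError(f"no events for test {test!r} in manifest")
    test_start = min(t for _, t in evs)
    end = test_start - gap_s
    start = end - window_s

    # baseline must not overlap the previous test's recovery: find the end
    # (event time + nominal phase duration) of the latest prior event
    prior_finish = -np.inf
    for tst, ph, t in manifest.events:
        if t < test_start and tst != test:
            dur = dict(get_test(tst).phases).get(ph, 0.0)
            prior_finish = max(prior_finish, t + dur)
    if start < prior_finish:
        start = prior_finish
    t0 = float(signal.t[0])
    if start < t0:
        start = t0
    if end - start < min_s:
        raise ProtocolError(
            f"only {end - start:.1f} s of baseline available before {test!r} "
            f"(need >= {min_s} s)"
        )
    sel = (signal.t >= start) & (signal.t <= end)
    v = signal.v[sel]
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise DataError(f"baseline window for {test!r} contains no samples")
    return BaselineStats(mu=float(np.mean(v)), sigma=float(np.std(v, ddof=1)),
                         window=(float(start), float(end)))


def extract_epoch(
    signal,
    epoch: Epoch,
    anchor_time: float,
    baseline: BaselineStats,
    *,
    mode: str = "divide",
    fs: float = EPOCH_FS,
    **meta,
) -> ResponseTrace:
    """Cut, baseline-normalize, and grid one epoch of a derived signal.

    ``mode='divide'`` gives fractional change (v − mu)/mu (the default,
    dimensionless and comparable across modalities); ``mode='subtract'``
    gives v − mu in the signal's own units. Samples past the end of the
    recorded signal are filled by holding the last observed value and marked
    in ``extrapolated``.
    """
    if mode not in ("divide", "subtract"):
        raise ConfigError(f"unknown normalization mode {mode!r}")
    if mode == "divide" and baseline.mu <= 0:
        raise DataError(
            f"baseline mean {baseline.mu} <= 0: cannot divide-normalize"
        )
    grid = epoch.grid(fs)
    t_abs = anchor_time + grid
    t_hi = float(signal.t[-1])
    finite = np.isfinite(signal.v)
    if not finite.all():
        # interpolate over NaN gaps (undefined RMSSD windows etc.)
        tt, vv = signal.t[finite], signal.v[finite]
    else:
        tt, vv = signal.t, signal.v
    if tt.size < 2:
        raise DataError("signal too short for epoch extraction")
    v = np.interp(t_abs, tt, vv)
    extrapolated = t_abs > min(t_hi, float(tt[-1]))
    if extrapolated.any():
        last = v[~extrapolated][-1] if (~extrapolated).any() else vv[-1]
        v[extrapolated] = last
        warnings.warn(
            f"epoch {epoch.name!r}: {int(extrapolated.sum())} samples "
            "extrapolated by holding last value",
            stacklevel=2,
        )
    if mode == "divide":
        y = (v - baseline.mu) / baseline.mu
    else:
        y = v - baseline.mu
    return ResponseTrace(t=grid, y=y, epoch=epoch.name, extrapolated=extrapolated, **meta)
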