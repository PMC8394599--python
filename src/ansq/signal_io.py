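"""Read and write raw sessions, manifests, and feature tables.

Raw channels are delimited text, one file per channel, with a single
comment header declaring name, units and sampling rate — the shape of a
typical chart-recorder export. The session manifest is YAML (or JSON) with
the subject covariates, the protocol event markers (seconds from recording
start), and the channel file paths. Feature tables are plain CSV with a
fixed column order and round-trip losslessly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .errors import ConfigError, DataError, ProtocolError
from .protocol import TEST_DEFINITIONS, get_test

__all__ = [
    "Recording",
    "SessionManifest",
    "FEATURE_COLUMNS",
    "load_recording",
    "load_session_manifest",
    "save_session_manifest",
    "write_channel",
    "read_channel",
    "write_feature_table",
    "read_feature_table",
    "validate_feature_table",
]

MANDATORY_CHANNELS = ("ECG", "BP")
OPTIONAL_CHANNELS = ("RESP", "EDA", "PUPIL", "GAZE")


@dataclass
class Recording:
    """Aligned raw channels at a common sampling rate.

    ``channels`` maps channel name to a sample array (GAZE is (N, 3) RGB in
    0–255; all others are 1-D in physical units: ECG mV, BP mmHg,
    respiration a.u., EDA µS, pupil mm).
    """

    channels: dict
    fs: float
    t0: float = 0.0
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")
        lengths = {k: np.asarray(v).shape[0] for k, v in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise DataError(f"channel lengths differ: {lengths}")

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).shape[0] if self.channels else 0

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class SessionManifest:
    """Protocol events and subject covariates for one testing session."""

    subject_id: str
    session_index: int
    time_of_day: str
    bmi: float
    age: float
    sex: str
    events: list  # (test, phase, t_seconds), ordered
    channel_paths: dict = field(default_factory=dict)
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if self.time_of_day not in ("AM", "PM"):
            raise ConfigError(
                f"time_of_day must be AM or PM, got {self.time_of_day!r}"
            )
        if not 1 <= int(self.session_index) <= 4:
            raise ConfigError("session_index must be in 1..4")
        self.events = [(str(a), str(b), float(c)) for a, b, c in self.events]
        self._validate_events()

    def _validate_events(self) -> None:
        times = [t for _, _, t in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ProtocolError("manifest events must be strictly increasing in time")
        seen: dict[str, list[str]] = {}
        for tst, ph, _ in self.events:
            if tst not in TEST_DEFINITIONS:
                raise ProtocolError(f"unknown test name {tst!r} in events")
            seen.setdefault(tst, []).append(ph)
        for tst, phases in seen.items():
            expected = list(get_test(tst).phase_names)
            if phases != expected:
                raise ProtocolError(
                    f"test {tst!r}: phases {phases} do not match protocol "
                    f"order {expected}"
                )

    def tests_present(self) -> list[str]:
        out = []
        for tst, _, _ in self.events:
            if tst not in out:
                out.append(tst)
        return out

    def phase_time(self, test: str, phase: str) -> float:
        for tst, ph, t in self.events:
            if tst == test and ph == phase:
                return t
        raise ProtocolError(f"no event for {test}/{phase}")


def write_channel(path, name: str, units: str, fs: float, values) -> None:
    """One channel per file: '# channel=.. units=.. fs=..' then samples."""
    values = np.asarray(values, dtype=float)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# channel={name} units={units} fs={fs:g}\n")
        if values.ndim == 1:
            np.savetxt(fh, values, fmt="%.6g")
        else:
            np.savetxt(fh, values, fmt="%.6g", delimiter=",")


def read_channel(path):
    """Read a channel file; returns (name, units, fs, values)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise DataError(f"{path}: missing channel header line")
        meta = dict(
            item.split("=", 1) for item in header[1:].split() if "=" in item
        )
        try:
            name = meta["channel"]
            units = meta["units"]
            fs = float(meta["fs"])
        except KeyError as exc:
            raise DataError(f"{path}: header missing {exc}") from None
        values = np.loadtxt(fh, delimiter="," if name == "GAZE" else None)
    return name, units, fs, np.atleast_1d(values)


def _fill_gaps(x: np.ndarray, fs: float, gap_limit_s: float, name: str) -> np.ndarray:
    """Linearly interpolate NaN runs up to ``gap_limit_s``; error beyond."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        bad = ~np.isfinite(x)
    else:
        bad = ~np.isfinite(x).all(axis=1)
    if not bad.any():
        return x
    # run-length scan for the longest NaN run
    idx = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
    starts, ends = idx[0::2], idx[1::2]
    longest = (ends - starts).max() / fs
    if longest > gap_limit_s:
        raise DataError(
            f"channel {name}: NaN gap of {longest:.2f} s exceeds limit "
            f"{gap_limit_s} s"
        )
    good = ~bad
    t = np.arange(x.shape[0])
    if x.ndim == 1:
        x = x.copy()
        x[bad] = np.interp(t[bad], t[good], x[good])
        return x
    x = x.copy()
    for j in range(x.shape[1]):
        x[bad, j] = np.interp(t[bad], t[good], x[good, j])
    return x


def _resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    if fs_in == fs_out:
        return x
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    if x.ndim == 1:
        return sps.resample_poly(x, up, down)
    return np.column_stack([sps.resample_poly(x[:, j], up, down)
                            for j in range(x.shape[1])])


def load_recording(paths, manifest: SessionManifest,
                   gap_limit_s: float = 1.0) -> Recording:
    """Load channel files, align to the manifest's common time base.

    ECG and BP are mandatory; pupil/gaze/EDA/respiration are optional and
    skipped with a warning when absent. Channels at a different sampling
    rate are resampled to the manifest rate; NaN runs up to 1 s (pupil
    blinks) are linearly interpolated.
    """
    channels: dict[str, np.ndarray] = {}
    units: dict[str, str] = {}
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise DataError(f"channel file not found: {p}")
        name, unit, fs, values = read_channel(p)
        values = _fill_gaps(values, fs, gap_limit_s, name)
        values = _resample(values, fs, manifest.fs)
        channels[name] = values
        units[name] = unit
    for name in MANDATORY_CHANNELS:
        if name not in channels:
            raise DataError(f"mandatory channel missing: {name}")
    for name in OPTIONAL_CHANNELS:
        if name not in channels:
            warnings.warn(
                f"optional channel {name} missing: modality skipped",
                stacklevel=2,
            )
    n = min(v.shape[0] for v in channels.values())
    n_max = max(v.shape[0] for v in channels.values())
    if n_max - n > manifest.fs:  # > 1 s mismatch is suspicious
        raise DataError("channel lengths differ by more than 1 s after resampling")
    channels = {k: v[:n] for k, v in channels.items()}
    return Recording(channels=channels, fs=manifest.fs, units=units)


def load_session_manifest(path) -> SessionManifest:
    """Parse and validate a YAML/JSON session manifest."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    try:
        events = [tuple(e) for e in raw["events"]]
        m = SessionManifest(
            subject_id=str(raw["subject"]),
            session_index=int(raw["session"]),
            time_of_day=str(raw["time_of_day"]),
            bmi=float(raw["bmi"]),
            age=float(raw["age"]),
            sex=str(raw["sex"]),
            events=events,
            channel_paths={
                k: str((path.parent / v)) for k, v in raw.get("channels", {}).items()
            },
            fs=float(raw.get("fs", 1000.0)),
        )
    except KeyError as exc:
        raise ConfigError(f"manifest {path}: missing key {exc}") from None
    return m


def save_session_manifest(manifest: SessionManifest, path) -> None:
    path = Path(path)
    doc = {
        "subject": manifest.subject_id,
        "session": int(manifest.session_index),
        "time_of_day": manifest.time_of_day,
        "bmi": float(manifest.bmi),
        "age": float(manifest.age),
        "sex": manifest.sex,
        "fs": float(manifest.fs),
        "events": [[t, p, float(s)] for t, p, s in manifest.events],
        "channels": {k: str(Path(v).name) for k, v in manifest.channel_paths.items()},
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))


FEATURE_COLUMNS = [
    "subject_id", "session_index", "time_of_day", "test", "epoch",
    "modality", "H", "Vs", "Vo", "V", "b_delay", "objective", "gated",
]


def validate_feature_table(table: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"feature table missing columns: {missing}")
    ungated = table[~table["gated"].astype(bool)]
    if len(ungated):
        vs = ungated["Vs"].to_numpy(dtype=float)
        vo = ungated["Vo"].to_numpy(dtype=float)
        v = ungated["V"].to_numpy(dtype=float)
        both = np.isfinite(vs) & np.isfinite(vo) & np.isfinite(v)
        if not np.allclose(v[both], vs[both] + vo[both], rtol=0, atol=1e-9):
            raise DataError("feature table violates V = Vs + Vo")
    gated = table[table["gated"].astype(bool)]
    for col in ("H", "Vs", "Vo", "V"):
        if len(gated) and np.isfinite(gated[col].to_numpy(dtype=float)).any():
            raise DataError("gated rows must carry no H/V values")


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write the feature CSV (fixed column order, lossless round-trip)."""
    validate_feature_table(table)
    out = table[FEATURE_COLUMNS].copy()
    out.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "time_of_day": str, "test": str,
               "epoch": str, "modality": str},
    )
    if list(df.columns) != FEATURE_COLUMNS:
        raise DataError(f"unexpected feature table columns: {list(df.columns)}")
    df["gated"] = df["gated"].astype(bool)
    df["session_index"] = df["session_index"].astype(int)
    validate_feature_table(df)
    return df
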