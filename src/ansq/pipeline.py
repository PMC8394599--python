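"""End-to-end orchestration: signals → traces → templates → features → stats.

``run_pipeline`` drives the full analysis either on simulated cohorts of
baseline-normalized response traces (``mode='traces'``, the default desk
workflow) or on raw multichannel session recordings listed by manifest
files (``mode='raw'``). Every stage writes its artifact into the output
directory and the run log records the effective configuration, seed and
library versions, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import AnsqError, ConfigError, DataError
from .indices import (DEFAULT_RULES, aggregate_participant, ampm_comparison,
                      classify_features, load_rules)
from .matching import (MatchConfig, deep_breathing_cohort_features,
                       fit_template)
from .preprocess import (DerivedSignal, compute_heart_rate, compute_map_series,
                         compute_rmssd_series, detect_r_peaks, normalize_pupil,
                         notch_filter, smooth_eda)
from .protocol import (RMSSD_TESTS, ResponseTrace, baseline_stats,
                       define_epochs, extract_epoch, get_test)
from .signal_io import (FEATURE_COLUMNS, load_recording,
                        load_session_manifest, write_feature_table)
from .stats import linear_regression_pvalue, repeated_kfold_cv_mape
from .synthetic import canonical_template, simulate_cohort
from .template import (build_average_template, pooled_baseline_sigma,
                       save_template, significance_gate)

__all__ = ["RunConfig", "run_pipeline", "extract_session_traces",
           "features_from_traces"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run (YAML-loadable)."""

    mode: str = "traces"  # 'traces' (simulated cohort) or 'raw' (manifests)
    seed: int = 0
    out_dir: str = "ansq_run"
    # cohort simulation (mode='traces')
    n_subjects: int = 21
    sessions_per_subject: int = 4
    beta: float = 0.05
    noise_sigma: float | None = None  # absolute; default: 0.1 × template peak
    noise_scale: float = 0.1
    #: restrict the simulated cohort to these (test, epoch, modality) cells;
    #: None simulates every canonical cell
    cells: list | None = None
    ampm_amp_gain: dict | None = None
    ampm_dur_gain: dict | None = None
    # raw mode
    manifests: list = field(default_factory=list)
    template_source: str = "average"  # or 'canonical'
    base_hr_fs: float = 4.0
    # gating / normalization
    gate_mode: str = "two_sided"
    gate_sigma: float | None = None  # traces mode: defaults to noise_sigma
    normalization: str = "divide"
    # matching
    match: dict = field(default_factory=dict)
    rules_file: str | None = None
    # statistics
    covariate: str = "bmi"
    cv_repeats: int = 10
    cv_folds: int = 7

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.mode not in ("traces", "raw"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "raw" and not self.manifests:
            raise ConfigError("raw mode requires the 'manifests' key")
        if self.rules_file is not None and not Path(self.rules_file).exists():
            raise ConfigError(f"rule file not found: {self.rules_file}")


def extract_session_traces(recording, manifest, fs_out: float = 4.0,
                           normalization: str = "divide"):
    """Raw recording → derived signals → baseline-normalized epoch traces.

    Returns (traces, baselines) where baselines maps (test, modality) to
    the BaselineStats used — the significance gate pools their σ. RMSSD is
    only derived for tests with analyzed intervals over 60 s. Modalities
    whose baseline is degenerate (zero mean) are skipped with a warning.
    """
    fs = recording.fs
    ecg = notch_filter(recording.channels["ECG"], fs)
    bp = notch_filter(recording.channels["BP"], fs)
    beats = detect_r_peaks(ecg, fs)
    signals: dict[str, DerivedSignal] = {
        "HR": compute_heart_rate(beats, fs_out),
        "MAP": compute_map_series(bp, fs, beats, fs_out),
    }
    try:
        signals["RMSSD"] = compute_rmssd_series(beats)
    except DataError as exc:
        warnings.warn(f"RMSSD unavailable: {exc}", stacklevel=2)
    if "EDA" in recording.channels:
        signals["EDA"] = smooth_eda(recording.channels["EDA"], fs)
    if "PUPIL" in recording.channels and "GAZE" in recording.channels:
        signals["PUPIL"] = normalize_pupil(
            recording.channels["PUPIL"], recording.channels["GAZE"],
            t=recording.t, fs=fs,
        )
    traces = []
    baselines = {}
    for test in manifest.tests_present():
        for modality, sig in signals.items():
            if modality == "RMSSD" and test not in RMSSD_TESTS:
                continue
            try:
                base = baseline_stats(sig, manifest, test)
            except (DataError, AnsqError) as exc:
                warnings.warn(f"{test}/{modality}: baseline unavailable "
                              f"({exc})", stacklevel=2)
                continue
            if normalization == "divide" and base.mu <= 0:
                warnings.warn(f"{test}/{modality}: nonpositive baseline mean;"
                              " modality skipped for this test", stacklevel=2)
                continue
            baselines[(test, modality)] = base
            for ep in define_epochs(test):
                anchor = manifest.phase_time(test, ep.anchor_phase)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    traces.append(extract_epoch(
                        sig, ep, anchor, base, mode=normalization,
                        modality=modality, test=test,
                        subject=manifest.subject_id,
                        session=manifest.session_index,
                        time_of_day=manifest.time_of_day,
                    ))
    return traces, baselines


def _db_hr_p2p(trace: ResponseTrace, cycle_s: float = 10.0) -> float:
    """Mean per-cycle peak-to-trough excursion of the paced-breathing trace."""
    t0 = trace.t[0]
    p2p = []
    for k in range(int(round((trace.t[-1] - t0) / cycle_s))):
        sel = (trace.t >= t0 + k * cycle_s) & (trace.t < t0 + (k + 1) * cycle_s)
        v = trace.y[sel & trace.observed]
        if v.size >= 3:
            p2p.append(float(v.max() - v.min()))
    if len(p2p) < 6:
        raise DataError("fewer than 6 usable breathing cycles")
    return float(np.mean(p2p))


def features_from_traces(traces, gate_sigma: float, *,
                         gate_mode: str = "two_sided",
                         match_config: MatchConfig | None = None,
                         template_source: str = "average",
                         covariates: dict | None = None):
    """Templates + gate + fits for a cohort of traces → feature table.

    Deep-breathing HR is special-cased: its feature is the per-cycle HR
    excursion normalized by the cohort mean (scale feature only, no
    duration), all other gated-in cells are template-matched. Returns
    (feature DataFrame, templates dict).
    """
    cfg = match_config or MatchConfig()
    by_cell: dict[tuple, list] = {}
    for tr in traces:
        by_cell.setdefault((tr.test, tr.epoch, tr.modality), []).append(tr)
    templates = {}
    for key, cell_traces in sorted(by_cell.items()):
        if template_source == "canonical":
            tpl = canonical_template(*key)
        else:
            tpl = build_average_template(cell_traces)
        significance_gate(tpl, gate_sigma, mode=gate_mode)
        templates[key] = tpl
    rows = []
    db_p2p: dict[tuple, float] = {}
    for key, cell_traces in sorted(by_cell.items()):
        tpl = templates[key]
        is_db_hr = key[0] == "deep_breathing" and key[2] == "HR"
        for tr in cell_traces:
            base = dict(subject_id=tr.subject, session_index=tr.session,
                        time_of_day=tr.time_of_day, test=tr.test,
                        epoch=tr.epoch, modality=tr.modality)
            if not tpl.sig:
                rows.append({**base, "H": np.nan, "Vs": np.nan, "Vo": np.nan,
                             "V": np.nan, "b_delay": np.nan,
                             "objective": np.nan, "gated": True})
                continue
            if is_db_hr:
                try:
                    db_p2p[(tr.subject, tr.session, tr.time_of_day)] = _db_hr_p2p(tr)
                except DataError as exc:
                    warnings.warn(f"deep-breathing HR {tr.subject}: {exc}",
                                  stacklevel=2)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = fit_template(tpl, tr, cfg)
            if not m.converged:
                continue
            rows.append({**base, "H": m.H, "Vs": m.Vs, "Vo": m.Vo, "V": m.V,
                         "b_delay": m.b, "objective": m.objective,
                         "gated": False})
    if db_p2p:
        key = ("deep_breathing", "first_2min", "HR")
        if templates.get(key) is not None and templates[key].sig:
            scaled = deep_breathing_cohort_features(db_p2p)
            for (subj, sess, tod), v in scaled.items():
                rows.append({
                    "subject_id": subj, "session_index": sess,
                    "time_of_day": tod, "test": "deep_breathing",
                    "epoch": "first_2min", "modality": "HR",
                    "H": np.nan, "Vs": v, "Vo": 0.0, "V": v,
                    "b_delay": np.nan, "objective": np.nan, "gated": False,
                })
    table = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return table, templates


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the report dict (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)

    covariates: dict[str, dict] = {}
    if config.mode == "traces":
        cells = ([tuple(c) for c in config.cells]
                 if config.cells is not None else None)
        traces, truth = simulate_cohort(
            n_subjects=config.n_subjects,
            sessions_per_subject=config.sessions_per_subject,
            cells=cells,
            beta=config.beta, noise_sigma=config.noise_sigma,
            noise_scale=config.noise_scale,
            ampm_amp_gain=config.ampm_amp_gain,
            ampm_dur_gain=config.ampm_dur_gain, seed=rng_seed,
        )
        covariates = {s: dict(bmi=d["bmi"], age=d["age"], sex=d["sex"])
                      for s, d in truth.subjects.items()}
        gate_sigma = (config.gate_sigma if config.gate_sigma is not None
                      else max(truth.noise_sigma, 1e-6))
    else:
        traces = []
        sigmas = []
        for mpath in config.manifests:
            manifest = load_session_manifest(mpath)
            paths = list(manifest.channel_paths.values())
            rec = load_recording(paths, manifest)
            tr, bases = extract_session_traces(
                rec, manifest, normalization=config.normalization)
            traces.extend(tr)
            sigmas.extend(bases.values())
            covariates[manifest.subject_id] = dict(
                bmi=manifest.bmi, age=manifest.age, sex=manifest.sex)
        gate_sigma = (config.gate_sigma if config.gate_sigma is not None
                      else pooled_baseline_sigma(sigmas))

    match_cfg = MatchConfig(**config.match) if config.match else MatchConfig()
    table, templates = features_from_traces(
        traces, gate_sigma, gate_mode=config.gate_mode,
        match_config=match_cfg, template_source=config.template_source
        if config.mode == "raw" else "average",
    )
    write_feature_table(table, out / "feature_table.csv")
    tdir = out / "templates"
    tdir.mkdir(exist_ok=True)
    for key, tpl in templates.items():
        save_template(tpl, tdir / ("{}_{}_{}.csv".format(*key)))

    rules = load_rules(config.rules_file) if config.rules_file else DEFAULT_RULES
    labeled = classify_features(table, rules)
    labeled.to_csv(out / "labeled_features.csv", index=False)
    summary = aggregate_participant(labeled)
    summary.to_csv(out / "participant_summary.csv", index=False)
    ampm = ampm_comparison(labeled)
    ampm.to_csv(out / "ampm_comparison.csv", index=False)

    report: dict = {
        "version": __version__,
        "seed": rng_seed,
        "n_traces": len(traces),
        "n_templates": len(templates),
        "gate_sigma": float(gate_sigma),
        "gated_out": [list(k) for k, t in templates.items() if not t.sig],
        "regression": {},
        "cv": {},
        "ampm": ampm.to_dict(orient="records"),
    }
    cov_name = config.covariate
    for group, sub in summary.groupby("group"):
        x, y = [], []
        for row in sub.itertuples(index=False):
            c = covariates.get(row.subject_id)
            if c is None or cov_name not in c:
                continue
            x.append(c[cov_name])
            y.append(row.mean)
        if len(x) >= 3 and np.ptp(x) > 0:
            res = linear_regression_pvalue(x, y, group=group, covariate=cov_name)
            report["regression"][group] = {
                "slope": res.slope, "intercept": res.intercept,
                "p_value": res.p_value, "t": res.t_statistic, "df": res.df,
                "n": len(x),
            }
            if len(x) >= config.cv_folds:
                cv = repeated_kfold_cv_mape(
                    np.asarray(y), np.asarray(x), repeats=config.cv_repeats,
                    folds=config.cv_folds, seed=rng_seed,
                )
                report["cv"][group] = {
                    "mean_mape": cv.mean_mape, "sd_mape": cv.sd_mape,
                    "repeats": cv.repeats, "folds": cv.folds,
                }

    cfg_dict = asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report["config_hash"] = cfg_hash
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    log = {"config": cfg_dict, "config_hash": cfg_hash,
           "versions": _versions()}
    (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=False))
    return report


def _versions() -> dict:
    import numpy
    import pandas
    import scipy
    return {"ansq": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__}
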