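"""Sympathetic/parasympathetic feature classification and aggregation.

Extracted duration (H) and amplitude (V) features are labeled as primarily
sympathetic (S) or parasympathetic (P) driven, by test, epoch and modality,
following the published classification of the five autonomic tests:
responses that raise heart rate or blood pressure are attributed to
sympathetic drive, bradycardic and HRV responses to parasympathetic drive.
Two special cases: in the squat test's stand epoch only V counts as
sympathetic and only H as parasympathetic, and deep breathing contributes a
single scale (V) feature to the parasympathetic side. Responses not
assignable to one branch are ignored.

The rule set lives in an editable mapping (and YAML round-trip) so an
alternative reading of the classification table is a config change, not a
code change. The Valsalva rows are marked ``interpreted``: their printed
layout in the source table is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError

__all__ = [
    "ClassificationRule",
    "DEFAULT_RULES",
    "GROUPS",
    "load_rules",
    "save_rules",
    "classify_features",
    "aggregate_participant",
    "ampm_comparison",
]

GROUPS = ("S-H", "S-V", "P-H", "P-V")


@dataclass(frozen=True)
class ClassificationRule:
    test: str
    epoch: str
    modality: str
    branch: str  # 'S' or 'P'
    feature_kinds: tuple[str, ...] = ("H", "V")
    note: str = ""

    def __post_init__(self) -> None:
        if self.branch not in ("S", "P"):
            raise ConfigError(f"branch must be S or P, got {self.branch!r}")
        if not self.feature_kinds:
            raise ConfigError("feature_kinds must be nonempty")
        if not set(self.feature_kinds) <= {"H", "V"}:
            raise ConfigError(f"feature_kinds must be within {{H, V}}")


def _r(test, epoch, modality, branch, kinds=("H", "V"), note=""):
    return ClassificationRule(test, epoch, modality, branch, tuple(kinds), note)


DEFAULT_RULES: tuple[ClassificationRule, ...] = (
    # squat test
    _r("squat", "squat", "HR", "S"),
    _r("squat", "squat", "MAP", "S"),
    _r("squat", "squat", "RMSSD", "P"),
    _r("squat", "stand", "HR", "S", ("V",)),
    _r("squat", "stand", "MAP", "S", ("V",)),
    _r("squat", "stand", "HR", "P", ("H",)),
    _r("squat", "stand", "MAP", "P", ("H",)),
    _r("squat", "stand", "RMSSD", "P", ("H",)),
    # cold pressor (pressor response; RMSSD not computed for this test)
    _r("cold_pressor", "hand_in", "MAP", "S"),
    _r("cold_pressor", "hand_out", "MAP", "S"),
    # diving reflex (bradycardia is parasympathetic)
    _r("diving_reflex", "mask_on", "MAP", "S"),
    _r("diving_reflex", "mask_on", "HR", "P"),
    _r("diving_reflex", "mask_on", "RMSSD", "P"),
    # Valsalva maneuver (printed classification ambiguous; best reading)
    _r("valsalva", "inhale", "MAP", "S", note="interpreted"),
    _r("valsalva", "vm", "MAP", "S", note="interpreted"),
    _r("valsalva", "vm", "HR", "P", note="interpreted"),
    _r("valsalva", "release", "MAP", "S", note="interpreted"),
    _r("valsalva", "release", "HR", "P", note="interpreted"),
    # deep breathing: single scale feature, parasympathetic
    _r("deep_breathing", "first_2min", "HR", "P", ("V",)),
    _r("deep_breathing", "first_2min", "RMSSD", "P", ("V",)),
)


def save_rules(rules, path) -> None:
    doc = [
        {"test": r.test, "epoch": r.epoch, "modality": r.modality,
         "branch": r.branch, "feature_kinds": list(r.feature_kinds),
         **({"note": r.note} if r.note else {})}
        for r in rules
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_rules(path) -> tuple[ClassificationRule, ...]:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, list):
        raise ConfigError(f"rule file {path}: expected a list of rules")
    rules = []
    for item in doc:
        try:
            rules.append(ClassificationRule(
                test=item["test"], epoch=item["epoch"],
                modality=item["modality"], branch=item["branch"],
                feature_kinds=tuple(item.get("feature_kinds", ("H", "V"))),
                note=item.get("note", ""),
            ))
        except KeyError as exc:
            raise ConfigError(f"rule file {path}: rule missing key {exc}") from None
    keys = [(r.test, r.epoch, r.modality, r.branch) for r in rules]
    if len(keys) != len(set(keys)):
        raise ConfigError("duplicate (test, epoch, modality, branch) rule")
    return tuple(rules)


def classify_features(
    table: pd.DataFrame,
    rules=DEFAULT_RULES,
    gated_out: set | None = None,
) -> pd.DataFrame:
    """Label feature rows by branch and kind; unmatched rows are ignored.

    Returns a long table with one row per (feature row, matched rule,
    feature kind): columns subject_id, session_index, time_of_day, test,
    epoch, modality, branch, kind, group, value. Gated rows are dropped. If
    ``gated_out`` (a set of (test, epoch, modality) that failed the
    significance gate) is given, a rule referencing one of them is a
    configuration error.
    """
    if gated_out:
        for r in rules:
            if (r.test, r.epoch, r.modality) in gated_out:
                raise ConfigError(
                    f"rule references gated-out modality "
                    f"{(r.test, r.epoch, r.modality)}"
                )
    index = {}
    for r in rules:
        index.setdefault((r.test, r.epoch, r.modality), []).append(r)
    out = []
    for row in table.itertuples(index=False):
        if bool(row.gated):
            continue
        for r in index.get((row.test, row.epoch, row.modality), ()):
            for kind in r.feature_kinds:
                value = getattr(row, kind)
                if value is None or not np.isfinite(value):
                    continue
                out.append({
                    "subject_id": row.subject_id,
                    "session_index": row.session_index,
                    "time_of_day": row.time_of_day,
                    "test": row.test,
                    "epoch": row.epoch,
                    "modality": row.modality,
                    "branch": r.branch,
                    "kind": kind,
                    "group": f"{r.branch}-{kind}",
                    "value": float(value),
                })
    cols = ["subject_id", "session_index", "time_of_day", "test", "epoch",
            "modality", "branch", "kind", "group", "value"]
    return pd.DataFrame(out, columns=cols)


def aggregate_participant(labeled: pd.DataFrame,
                          by_time_of_day: bool = False) -> pd.DataFrame:
    """Per-subject mean ± SD of each feature group over all sessions.

    SD is the sample SD; a single contributing feature yields SD 0.
    """
    if labeled.empty:
        raise DataError("no labeled features to aggregate")
    keys = ["subject_id", "group"] + (["time_of_day"] if by_time_of_day else [])
    agg = (
        labeled.groupby(keys)["value"]
        .agg(mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
             n_features="count")
        .reset_index()
    )
    return agg


def ampm_comparison(labeled: pd.DataFrame) -> pd.DataFrame:
    """Count subjects per group whose AM mean exceeds their PM mean and v.v.

    Subjects lacking either AM or PM sessions for a group are excluded;
    exact ties count to neither side and are reported separately.
    """
    per = aggregate_participant(labeled, by_time_of_day=True)
    rows = []
    for group, sub in per.groupby("group"):
        wide = sub.pivot(index="subject_id", columns="time_of_day", values="mean")
        eligible = wide.dropna(subset=[c for c in ("AM", "PM") if c in wide.columns]) \
            if {"AM", "PM"} <= set(wide.columns) else wide.iloc[0:0]
        n_am = int((eligible["AM"] > eligible["PM"]).sum()) if len(eligible) else 0
        n_pm = int((eligible["PM"] > eligible["AM"]).sum()) if len(eligible) else 0
        n_tie = len(eligible) - n_am - n_pm
        rows.append({"group": group, "n_am_higher": n_am,
                     "n_pm_higher": n_pm, "n_ties": n_tie,
                     "n_eligible": len(eligible)})
    return pd.DataFrame(rows, columns=["group", "n_am_higher", "n_pm_higher",
                                       "n_ties", "n_eligible"])
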