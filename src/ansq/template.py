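"""Cohort average-response templates and the 1σ significance gate.

For every (test, epoch, modality) the baseline-normalized individual
responses are averaged pointwise across participants and sessions to form
the template f(x), anchored at the epoch event x0. Only templates whose
peak deviation exceeds one baseline standard deviation (in the same
normalized units) are considered significant; modalities failing this gate
— as electrodermal activity and pupil diameter did in the healthy cohort —
are excluded from feature extraction.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError
from .protocol import ResponseTrace

__all__ = [
    "Template",
    "build_average_template",
    "significance_gate",
    "pooled_baseline_sigma",
    "save_template",
    "load_template",
]


@dataclass
class Template:
    """Average baseline-normalized response on an epoch grid.

    ``sig`` is the significance-gate verdict: None until gated, False when
    the peak never clears 1σ of pooled baseline variability (downstream
    fitting then refuses this modality/test), True otherwise.
    """

    t: np.ndarray
    f: np.ndarray
    x0: float = 0.0
    n_traces: int = 1
    ci95: np.ndarray | None = None
    sig: bool | None = None
    baseline_sigma_pooled: float | None = None
    test: str = ""
    epoch: str = ""
    modality: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.t.shape != self.f.shape:
            raise DataError("template t and f must share a shape")
        if self.n_traces < 1:
            raise DataError("template needs at least one contributing trace")
        if self.ci95 is not None:
            self.ci95 = np.asarray(self.ci95, dtype=float)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.test, self.epoch, self.modality)


def build_average_template(traces: list[ResponseTrace]) -> Template:
    """Pointwise mean of baseline-normalized traces (95% CI alongside).

    All traces must share (test, epoch, modality) and grid. Extrapolated
    samples (e.g. after early hand removal in the cold pressor test) are
    excluded pointwise, so the average at each time reflects only the
    individual traces actually observed there.
    """
    if len(traces) < 2:
        raise DataError("need at least 2 traces to average a template")
    first = traces[0]
    key = (first.test, first.epoch, first.modality)
    grid = first.t
    ys = []
    masks = []
    for tr in traces:
        if (tr.test, tr.epoch, tr.modality) != key:
            raise DataError(
                f"trace {(tr.test, tr.epoch, tr.modality)} does not match {key}"
            )
        if tr.t.shape != grid.shape or not np.allclose(tr.t, grid):
            raise DataError("trace grids mismatch; cannot average")
        ys.append(tr.y)
        masks.append(tr.observed)
    Y = np.vstack(ys)
    M = np.vstack(masks)
    n_pt = M.sum(axis=0)
    if (n_pt == 0).any():
        raise DataError("no observed samples at some grid points")
    Ym = np.where(M, Y, 0.0)
    mean = Ym.sum(axis=0) / n_pt
    # pointwise sample SD over contributing traces; SE -> 95% CI half-width
    dev = np.where(M, Y - mean, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (dev**2).sum(axis=0) / np.maximum(n_pt - 1, 1)
        se = np.sqrt(var / n_pt)
    ci95 = np.where(n_pt > 1, 1.96 * se, 0.0)
    return Template(
        t=grid.copy(), f=mean, x0=0.0, n_traces=len(traces), ci95=ci95,
        test=key[0], epoch=key[1], modality=key[2],
    )


def pooled_baseline_sigma(baselines) -> float:
    """Pool per-session baseline SDs (normalized units) by root-mean-square.

    Each baseline contributes sigma/mu — its SD expressed in the same
    fractional-change units as the traces. The gate compares the cohort
    average response against this pooled σ.
    """
    vals = np.array([b.sigma_normalized for b in baselines], dtype=float)
    if vals.size == 0:
        raise DataError("no baselines to pool")
    return float(np.sqrt(np.mean(vals**2)))


def significance_gate(
    template: Template,
    baseline_sigma: float,
    *,
    mode: str = "two_sided",
) -> bool:
    """Apply the 1σ significance threshold and stamp the verdict.

    True iff the template's peak deviation from the baseline level (0 in
    normalized units) exceeds one pooled baseline SD. Two-sided by default:
    bradycardic responses (e.g. diving-reflex HR) deviate downward and would
    otherwise be discarded along with genuinely flat modalities. A
    ``one_sided`` mode gates on the positive peak only.
    """
    if baseline_sigma < 0:
        raise DataError("baseline sigma must be >= 0")
    if mode == "two_sided":
        peak = float(np.max(np.abs(template.f)))
    elif mode == "one_sided":
        peak = float(np.max(template.f))
    else:
        raise DataError(f"unknown gate mode {mode!r}")
    if baseline_sigma == 0.0 and peak > 0:
        warnings.warn(
            "zero baseline sigma with non-flat template: gate passes "
            "trivially", stacklevel=2,
        )
        verdict = True
    else:
        verdict = peak > baseline_sigma
    template.sig = verdict
    template.baseline_sigma_pooled = float(baseline_sigma)
    return verdict


_HEADER_KEYS = ("test", "epoch", "modality", "x0", "n_traces", "sig",
                "baseline_sigma_pooled")


def save_template(template: Template, path) -> None:
    """Serialize to a portable text table (# key=value header + columns)."""
    path = Path(path)
    buf = io.StringIO()
    for k in _HEADER_KEYS:
        buf.write(f"# {k}={getattr(template, k)}\n")
    ci = template.ci95 if template.ci95 is not None else np.zeros_like(template.f)
    buf.write("t,f,ci95\n")
    for t, f, c in zip(template.t, template.f, ci):
        buf.write(f"{float(t)!r},{float(f)!r},{float(c)!r}\n")
    path.write_text(buf.getvalue())


def load_template(path) -> Template:
    path = Path(path)
    meta: dict = {}
    rows = []
    header_seen = False
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
        elif not header_seen:
            header_seen = True  # column header line
        elif line.strip():
            rows.append([float(x) for x in line.split(",")])
    arr = np.array(rows, dtype=float)
    sig_raw = meta.get("sig", "None")
    sig = None if sig_raw == "None" else sig_raw == "True"
    bsp_raw = meta.get("baseline_sigma_pooled", "None")
    bsp = None if bsp_raw == "None" else float(bsp_raw)
    return Template(
        t=arr[:, 0], f=arr[:, 1], ci95=arr[:, 2],
        x0=float(meta.get("x0", 0.0)),
        n_traces=int(meta.get("n_traces", 1)),
        sig=sig, baseline_sigma_pooled=bsp,
        test=meta.get("test", ""), epoch=meta.get("epoch", ""),
        modality=meta.get("modality", ""),
    )
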