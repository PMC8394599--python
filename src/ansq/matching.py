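"""Template matching of individual autonomic responses.

The cohort average response f(x), anchored at the epoch event time x0, is
fitted to an individual's baseline-normalized response y by minimizing the
normalized sum of squared errors

    J(a, b, c, d) = || c·f(a(x − x0) + x0 − b) + d − y ||²  /  VAR(g),

where g = c·f(a(x − x0) + x0 − b) + d and VAR is the population variance of
g over the evaluation grid. The four parameters have direct physiological
readings: *a* stretches/compresses the response in time, *b* delays or
advances it, *c* scales its amplitude (reported as Vs), and *d* offsets it
vertically (reported as Vo). The reported features are the duration scale
H and the net amplitude V = Vs + Vo.

Two H conventions are supported. Under the literal transform, a > 1 means
the template is *sped up* to match a shorter response, so the intuitive
"duration multiplier" of the individual response is 1/a. The default
``duration`` convention reports H = 1/a (H < 1 ⇔ response faster/shorter
than average); ``literal_a`` reports H = a.

Key structural fact exploited by the optimizer: for fixed (a, b) the
objective is minimized in closed form over (c, d). Writing u for the warped
template and ỹ, ũ for the mean-removed y and u on the evaluation grid,

    c* = ‖ỹ‖² / (ũ·ỹ),   d* = mean(y) − c*·mean(u),

and the profiled objective equals N·(1 − r²) with r the Pearson correlation
of u and y. The multi-start local search therefore runs in the (a, b) plane
only, with a bounded 4-D polish when c*, d* land outside their bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .errors import ConfigError, DataError
from .protocol import ResponseTrace
from .template import Template

__all__ = [
    "MatchConfig",
    "MatchResult",
    "transform_template",
    "objective_value",
    "fit_template",
    "brute_force_fit",
    "deep_breathing_feature",
    "deep_breathing_cohort_features",
]


@dataclass(frozen=True)
class MatchConfig:
    """Bounds, restarts and conventions for template fitting."""

    a_bounds: tuple[float, float] = (0.2, 5.0)
    #: b bounds as a fraction of epoch length (±)
    b_fraction: float = 0.5
    c_bounds: tuple[float, float] = (-5.0, 5.0)
    d_bounds: tuple[float, float] = (-1.0, 1.0)
    a_starts: tuple[float, ...] = (0.5, 1.0, 2.0)
    b_starts: tuple[float, ...] = (-5.0, 0.0, 5.0)
    #: 'duration' reports H = 1/a (duration multiplier); 'literal_a' reports H = a
    convention: str = "duration"
    var_floor: float = 1e-8
    xatol: float = 1e-5
    fatol: float = 1e-10
    maxiter: int = 400
    #: stop launching restarts once a start reaches this objective (an
    #: essentially exact fit; further restarts cannot improve the features)
    early_stop_objective: float = 1e-9
    #: stop after this many consecutive restarts fail to improve the best
    #: minimum (they keep landing in the same basin); 0 disables
    patience: int = 3
    #: objective above this is flagged as a poor fit (normalized units; the
    #: profiled objective is N(1 − r²) ≤ N, so this is ~N·(1 − 0.25))
    poor_fit_r2: float = 0.25

    def __post_init__(self) -> None:
        if self.convention not in ("duration", "literal_a"):
            raise ConfigError(f"unknown H convention {self.convention!r}")
        if self.a_bounds[0] <= 0:
            raise ConfigError("a lower bound must be positive")

    def h_from_a(self, a: float) -> float:
        return 1.0 / a if self.convention == "duration" else a

    def a_from_h(self, h: float) -> float:
        return 1.0 / h if self.convention == "duration" else h


@dataclass
class MatchResult:
    """Fitted transform parameters and the reported features.

    ``a, b, c, d`` are the raw transform parameters; ``H`` is the duration
    feature under the configured convention, ``Vs = c``, ``Vo = d`` and
    ``V = Vs + Vo`` the amplitude features.
    """

    a: float
    b: float
    c: float
    d: float
    H: float
    objective: float
    n_restarts_used: int = 0
    converged: bool = True
    poor_fit: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise DataError("duration parameter a must be positive")
        if self.objective < 0:
            raise DataError("objective must be nonnegative")

    @property
    def Vs(self) -> float:
        return self.c

    @property
    def Vo(self) -> float:
        return self.d

    @property
    def V(self) -> float:
        return self.c + self.d


def _warp(template: Template, a: float, b: float, t: np.ndarray) -> np.ndarray:
    """Evaluate f(a(t − x0) + x0 − b) with edge-value extension."""
    xq = a * (t - template.x0) + template.x0 - b
    return np.interp(xq, template.t, template.f)


def transform_template(
    template: Template, a: float, b: float, c: float, d: float,
    t: np.ndarray | None = None,
) -> np.ndarray:
    """g(x) = c·f(a(x − x0) + x0 − b) + d on the epoch grid (or ``t``)."""
    if a <= 0:
        raise DataError("duration parameter a must be positive")
    if t is None:
        t = template.t
    return c * _warp(template, a, b, np.asarray(t, dtype=float)) + d


def objective_value(
    template: Template,
    trace: ResponseTrace,
    a: float,
    b: float,
    c: float,
    d: float,
    var_floor: float = 1e-8,
) -> float:
    """Normalized SSE ‖g − y‖²/VAR(g), restricted to observed samples.

    Returns +inf when the transformed template is (near-)constant on the
    evaluation grid: a flat candidate carries no shape information and the
    normalization would otherwise be singular.
    """
    mask = trace.observed
    g = transform_template(template, a, b, c, d, t=trace.t[mask])
    var = float(np.var(g))  # population variance
    if var < var_floor:
        return float("inf")
    resid = g - trace.y[mask]
    return float(resid @ resid / var)


def _profile_cd(u: np.ndarray, y: np.ndarray, var_floor: float):
    """Closed-form (c*, d*) and objective for a fixed warped template u."""
    n = u.size
    mu_u = u.mean()
    mu_y = y.mean()
    ut = u - mu_u
    yt = y - mu_y
    uu = float(ut @ ut)
    if uu / n < var_floor:
        return np.nan, np.nan, float("inf")
    yy = float(yt @ yt)
    s = float(ut @ yt)
    if yy <= 0.0 or s == 0.0:
        # y constant or exactly orthogonal: no informative amplitude
        return np.nan, np.nan, float("inf")
    c = yy / s
    d = mu_y - c * mu_u
    # J = N(1 − r²)
    obj = n * max(0.0, 1.0 - s * s / (uu * yy))
    return c, d, obj


def fit_template(
    template: Template,
    trace: ResponseTrace,
    config: MatchConfig | None = None,
) -> MatchResult:
    """Fit the Eq-style transform by bounded multi-start local search.

    Requires ``template.sig`` (the 1σ significance gate) to be true. Starts
    span a ∈ {0.5, 1, 2} × b ∈ {−5, 0, 5} s (clipped to bounds); each start
    runs Nelder–Mead over (a, b) with (c, d) profiled out in closed form,
    followed by a bounded 4-D polish whenever the profiled (c, d) violate
    their bounds.
    """
    if template.sig is False:
        raise DataError(
            f"template {template.key} failed the significance gate; "
            "feature extraction refused"
        )
    cfg = config or MatchConfig()
    mask = trace.observed
    if mask.sum() < 8:
        raise DataError("too few observed samples in trace to fit")
    t_obs = trace.t[mask]
    y_obs = trace.y[mask]
    epoch_len = float(trace.t[-1] - trace.t[0])
    b_lo, b_hi = -cfg.b_fraction * epoch_len, cfg.b_fraction * epoch_len
    a_lo, a_hi = cfg.a_bounds

    # precompute for fast warping inside the objective
    tpl_t, tpl_f, x0 = template.t, template.f, template.x0

    def warped(a: float, b: float) -> np.ndarray:
        return np.interp(a * (t_obs - x0) + x0 - b, tpl_t, tpl_f)

    # statistics of y are fixed across evaluations: hoist them
    n_obs_f = float(t_obs.size)
    mu_y = float(y_obs.mean())
    yt = y_obs - mu_y
    yy = float(yt @ yt)

    def prof_obj(p: np.ndarray) -> float:
        a, b = p
        if not (a_lo <= a <= a_hi and b_lo <= b <= b_hi):
            return float("inf")
        u = warped(a, b)
        ut = u - u.mean()
        uu = float(ut @ ut)
        if uu / n_obs_f < cfg.var_floor:
            return float("inf")
        s = float(ut @ yt)
        if yy <= 0.0 or s == 0.0:
            return float("inf")
        return n_obs_f * max(0.0, 1.0 - s * s / (uu * yy))

    best = None
    n_used = 0
    no_improve = 0
    starts = [(float(np.clip(a0, a_lo, a_hi)), float(np.clip(b0, b_lo, b_hi)))
              for a0 in cfg.a_starts for b0 in cfg.b_starts]
    # coarse presearch of the profiled objective ranks the candidate
    # starts, so local searches launch best-basin-first and the
    # no-improvement stop cannot fire before the most promising regions
    # have been probed
    a_grid = np.geomspace(a_lo, a_hi, 13)
    b_grid = np.linspace(b_lo, b_hi, 41)
    cand: list[tuple[float, float, float]] = []
    for a in a_grid:
        base = a * (t_obs - x0) + x0
        u = np.interp((base[None, :] - b_grid[:, None]).ravel(),
                      tpl_t, tpl_f).reshape(b_grid.size, t_obs.size)
        ut = u - u.mean(axis=1, keepdims=True)
        uu = np.einsum("ij,ij->i", ut, ut)
        s = ut @ yt
        with np.errstate(divide="ignore", invalid="ignore"):
            obj = t_obs.size * np.maximum(0.0, 1.0 - s * s / (uu * yy))
        obj = np.where((uu / t_obs.size < cfg.var_floor) | (s == 0.0)
                       | (yy <= 0.0), np.inf, obj)
        cand.extend(zip(obj, (float(a),) * b_grid.size, b_grid))
    cand.extend((prof_obj(np.array(s)), s[0], s[1]) for s in starts)
    cand.sort(key=lambda s: s[0])
    n_ranked = 5
    ranked = [(float(a), float(b)) for _, a, b in cand[:n_ranked]]
    starts = ranked + [s for s in starts if s not in ranked]
    for idx, (a0, b0) in enumerate(starts):
        if best is not None and best.fun <= cfg.early_stop_objective:
            break
        # the ranked starts are always polished; patience only prunes the
        # remaining fixed starts once the best basins have been probed
        if (cfg.patience and idx >= n_ranked
                and no_improve >= cfg.patience):
            break
        n_used += 1
        res = minimize(
            prof_obj,
            np.array([a0, b0]),
            method="Nelder-Mead",
            bounds=[(a_lo, a_hi), (b_lo, b_hi)],
            options=dict(
                xatol=cfg.xatol, fatol=cfg.fatol, maxiter=cfg.maxiter
            ),
        )
        if not np.isfinite(res.fun):
            no_improve += 1
            continue
        if best is None or res.fun < best.fun - max(1e-9, 1e-6 * abs(best.fun)):
            best = res
            no_improve = 0
        else:
            no_improve += 1
    if best is None:
        return MatchResult(
            a=1.0, b=0.0, c=0.0, d=0.0, H=cfg.h_from_a(1.0),
            objective=float("inf"), n_restarts_used=n_used, converged=False,
        )
    a, b = float(best.x[0]), float(best.x[1])
    a = float(np.clip(a, a_lo, a_hi))
    b = float(np.clip(b, b_lo, b_hi))
    c, d, obj = _profile_cd(warped(a, b), y_obs, cfg.var_floor)

    c_lo, c_hi = cfg.c_bounds
    d_lo, d_hi = cfg.d_bounds
    if not (np.isfinite(c) and c_lo <= c <= c_hi and d_lo <= d <= d_hi):
        # profiled amplitude/offset out of bounds: bounded 4-D polish
        c0 = float(np.clip(np.nan_to_num(c, nan=1.0), c_lo, c_hi))
        d0 = float(np.clip(np.nan_to_num(d, nan=0.0), d_lo, d_hi))

        def full_obj(p: np.ndarray) -> float:
            aa, bb, cc, dd = p
            if aa <= 0:
                return float("inf")
            g = cc * np.interp(aa * (t_obs - x0) + x0 - bb, tpl_t, tpl_f) + dd
            var = float(np.var(g))
            if var < cfg.var_floor:
                return float("inf")
            r = g - y_obs
            return float(r @ r / var)

        res4 = minimize(
            full_obj,
            np.array([a, b, c0, d0]),
            method="Nelder-Mead",
            bounds=[(a_lo, a_hi), (b_lo, b_hi), (c_lo, c_hi), (d_lo, d_hi)],
            options=dict(xatol=cfg.xatol, fatol=cfg.fatol,
                         maxiter=4 * cfg.maxiter),
        )
        a, b, c, d = (float(v) for v in res4.x)
        obj = float(res4.fun)

    if not np.isfinite(obj):
        return MatchResult(
            a=1.0, b=0.0, c=0.0, d=0.0, H=cfg.h_from_a(1.0),
            objective=float("inf"), n_restarts_used=n_used, converged=False,
        )
    n_obs = int(mask.sum())
    poor = obj > n_obs * (1.0 - cfg.poor_fit_r2)
    if c < 0:
        warnings.warn(
            f"inverted response (c = {c:.3g}) fitted for {template.key}",
            stacklevel=2,
        )
    return MatchResult(
        a=a, b=b, c=c, d=d, H=cfg.h_from_a(a), objective=obj,
        n_restarts_used=n_used, converged=True, poor_fit=poor,
    )


def brute_force_fit(
    template: Template,
    trace: ResponseTrace,
    a_grid,
    b_grid,
    c_grid,
    d_grid,
    config: MatchConfig | None = None,
) -> MatchResult:
    """Exhaustive grid minimum of the objective (test oracle).

    Evaluates the objective at every grid point and returns the minimizer;
    by construction no optimizer restart can beat it *on the grid*.
    """
    cfg = config or MatchConfig()
    mask = trace.observed
    t_obs = trace.t[mask]
    y_obs = trace.y[mask]
    tpl_t, tpl_f, x0 = template.t, template.f, template.x0
    c_arr = np.asarray(c_grid, dtype=float)[:, None]
    d_arr = np.asarray(d_grid, dtype=float)[None, :]
    best_obj = float("inf")
    best_params = (1.0, 0.0, 1.0, 0.0)
    for a in np.asarray(a_grid, dtype=float):
        if a <= 0:
            continue
        for b in np.asarray(b_grid, dtype=float):
            u = np.interp(a * (t_obs - x0) + x0 - b, tpl_t, tpl_f)
            # vectorized over the (c, d) plane
            g = c_arr[..., None] * u[None, None, :] + d_arr[..., None]
            var = g.var(axis=-1)
            sse = ((g - y_obs[None, None, :]) ** 2).sum(axis=-1)
            with np.errstate(divide="ignore", invalid="ignore"):
                obj = np.where(var >= cfg.var_floor, sse / var, np.inf)
            k = np.unravel_index(np.argmin(obj), obj.shape)
            if obj[k] < best_obj:
                best_obj = float(obj[k])
                best_params = (float(a), float(b), float(c_arr[k[0], 0]),
                               float(d_arr[0, k[1]]))
    a, b, c, d = best_params
    return MatchResult(a=a, b=b, c=c, d=d, H=cfg.h_from_a(a),
                       objective=best_obj, n_restarts_used=0, converged=True)


def _breath_cycles_from_resp(resp_t, resp_v, t_start, t_end, fs_min=1.0):
    """Breathing cycle boundaries from upward zero-crossings of respiration.

    The respiration channel is mean-removed over the analysis window first;
    paced breathing at 6/min yields ~12 cycles in 2 min.
    """
    sel = (resp_t >= t_start) & (resp_t <= t_end)
    t = resp_t[sel]
    v = resp_v[sel]
    if t.size < 8:
        return []
    v = v - np.mean(v)
    up = np.flatnonzero((v[:-1] <= 0) & (v[1:] > 0))
    bounds = t[up]
    # discard implausibly short cycles (< 4 s at 6 breaths/min pacing)
    cycles = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e - s >= 4.0:
            cycles.append((float(s), float(e)))
    return cycles


def deep_breathing_feature(
    hr,
    resp=None,
    *,
    t_start: float = 0.0,
    duration: float = 120.0,
    cohort_mean_p2p: float | None = None,
    min_cycles: int = 6,
):
    """Per-individual deep-breathing amplitude feature.

    The peak-to-trough HR excursion of each paced breathing cycle in the
    first two minutes is averaged; dividing by the cohort-average excursion
    (``cohort_mean_p2p``) yields the scale-like feature V. With
    ``cohort_mean_p2p=None`` the raw mean excursion (bpm) is returned, to be
    normalized at cohort level. No duration feature exists for this test:
    pacing entrains every individual to the same cycle timing.

    Cycles are segmented from the respiration channel when available,
    falling back to fixed 10 s windows (6 breaths/min pacing).
    """
    t_end = t_start + duration
    cycles = []
    if resp is not None:
        cycles = _breath_cycles_from_resp(resp.t, resp.v, t_start, t_end)
    if len(cycles) < min_cycles:
        edges = np.arange(t_start, t_end + 1e-9, 10.0)
        cycles = list(zip(edges[:-1], edges[1:]))
    p2p = []
    for s, e in cycles:
        sel = (hr.t >= s) & (hr.t < e)
        v = hr.v[sel]
        v = v[np.isfinite(v)]
        if v.size >= 3:
            p2p.append(float(v.max() - v.min()))
    if len(p2p) < min_cycles:
        raise DataError(
            f"only {len(p2p)} usable breathing cycles (< {min_cycles}); "
            "deep-breathing feature withheld"
        )
    mean_p2p = float(np.mean(p2p))
    if cohort_mean_p2p is None:
        return mean_p2p
    if cohort_mean_p2p <= 0:
        raise DataError("cohort mean peak-to-peak HR must be positive")
    return mean_p2p / cohort_mean_p2p


def deep_breathing_cohort_features(mean_p2p_by_subject: dict) -> dict:
    """Normalize per-individual mean HR excursions by the cohort mean.

    The returned features average exactly to 1 over the cohort.
    """
    vals = np.array(list(mean_p2p_by_subject.values()), dtype=float)
    if vals.size == 0:
        raise DataError("no deep-breathing excursions supplied")
    denom = float(vals.mean())
    if denom <= 0:
        raise DataError("cohort mean peak-to-peak HR must be positive")
    return {k: v / denom for k, v in mean_p2p_by_subject.items()}
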