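"""Covariate correlation and cross-validated prediction of covariates.

Per-subject group-mean features are regressed on a covariate (BMI by
default) with an ordinary least-squares line; significance comes from the
two-sided t statistic of the slope with n − 2 degrees of freedom. The
trend is validated by repeated k-fold cross-validation: within each fold
the regression is fitted on the training subjects and the *trend line is
inverted* to predict the covariate of the held-out subjects; accuracy is
summarized as the mean absolute percentage error (MAPE) per repeat, with
subjects reshuffled between repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sst

from .errors import ConfigError, DataError

__all__ = ["RegressionResult", "CVReport", "linear_regression_pvalue",
           "repeated_kfold_cv_mape"]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    p_value: float
    t_statistic: float
    df: int
    stderr: float = float("nan")
    group: str = ""
    covariate: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DataError("p-value outside [0, 1]")


@dataclass
class CVReport:
    repeats: int
    folds: int
    mape_per_repeat: np.ndarray
    mean_mape: float
    sd_mape: float
    n_skipped_folds: int = 0
    direction: str = "invert"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ConfigError("need at least 2 folds")
        self.mape_per_repeat = np.asarray(self.mape_per_repeat, dtype=float)


def linear_regression_pvalue(x, y, group: str = "",
                             covariate: str = "") -> RegressionResult:
    """OLS fit of y on x with a two-sided t-test on the slope.

    An exact linear fit (zero residual) has zero slope standard error; the
    t statistic is infinite and the p-value is reported as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise DataError("need at least 3 points for the slope t-test")
    if np.ptp(x) == 0:
        raise DataError("covariate is constant; slope undefined")
    res = sst.linregress(x, y)
    df = n - 2
    if res.stderr == 0.0 or not np.isfinite(res.stderr):
        tstat = float("inf") if res.slope != 0 else 0.0
        p = 0.0 if res.slope != 0 else 1.0
    else:
        tstat = res.slope / res.stderr
        p = 2.0 * sst.t.sf(abs(tstat), df)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        p_value=float(p), t_statistic=float(tstat), df=df,
        stderr=float(res.stderr), group=group, covariate=covariate,
    )


def _fold_indices(n: int, folds: int, rng: np.random.Generator):
    """Shuffled near-equal split of subject indices into folds."""
    perm = rng.permutation(n)
    return np.array_split(perm, folds)


def repeated_kfold_cv_mape(
    features,
    covariate,
    repeats: int = 10,
    folds: int = 7,
    seed: int = 0,
    direction: str = "invert",
    min_slope: float = 1e-12,
) -> CVReport:
    """Repeated k-fold CV of covariate prediction from a feature.

    ``direction='invert'`` fits feature = m·covariate + b on the training
    subjects and predicts covariate = (feature − b)/m for held-out subjects
    (inverting the trend line); ``direction='direct'`` regresses the
    covariate on the feature instead. MAPE (%) is computed per repeat over
    all held-out predictions; folds whose training slope is numerically
    zero are skipped (inversion unstable) and counted. Subject-level
    splitting: each subject appears in exactly one test fold per repeat,
    reshuffled every repeat. Deterministic for a given seed.
    """
    y = np.asarray(features, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise DataError("features and covariate must be 1-D of equal length")
    n = y.size
    if n < folds:
        raise ConfigError(f"cannot split {n} subjects into {folds} folds")
    if direction not in ("invert", "direct"):
        raise ConfigError(f"unknown CV direction {direction!r}")
    if np.any(x == 0):
        raise DataError("covariate contains zeros; MAPE undefined")
    rng = np.random.default_rng(seed)
    mapes = []
    skipped = 0
    for _ in range(repeats):
        abs_pct = []
        for test_idx in _fold_indices(n, folds, rng):
            train = np.setdiff1d(np.arange(n), test_idx)
            xt, yt = x[train], y[train]
            if direction == "invert":
                m, b = np.polyfit(xt, yt, 1)
                if abs(m) < min_slope:
                    skipped += 1
                    continue
                pred = (y[test_idx] - b) / m
            else:
                m, b = np.polyfit(yt, xt, 1)
                pred = m * y[test_idx] + b
            abs_pct.extend(np.abs(pred - x[test_idx]) / np.abs(x[test_idx]))
        if not abs_pct:
            raise DataError("all folds skipped; cannot compute MAPE")
        mapes.append(100.0 * float(np.mean(abs_pct)))
    mapes = np.asarray(mapes)
    return CVReport(
        repeats=repeats, folds=folds, mape_per_repeat=mapes,
        mean_mape=float(mapes.mean()),
        sd_mape=float(mapes.std(ddof=1)) if repeats > 1 else 0.0,
        n_skipped_folds=skipped, direction=direction,
    )
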