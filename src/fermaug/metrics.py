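"""Prediction metrics and the two-sample tests used to compare regimes.

R-squared here is the generalized coefficient of determination
(1 - SS_res/SS_tot), which goes negative whenever predictions are worse
than the mean of the observations.  Adjusted R-squared uses the number of
training *sets* (whole experiments) as N, not individual timesteps: with a
fixed predictor count p, that is the quantity that changes between the
augmentation regimes.  Welch's unequal-variance t-test compares metric
means across regimes and the Levene test (mean-centered) compares their
variances; both delegate to scipy.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "r_squared",
    "adjusted_r_squared",
    "mean_absolute_error",
    "rmse",
    "percent_change",
    "welch_t_test",
    "levene_test",
]


def _paired(y, y_hat, min_len=1):
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size < min_len:
        raise ValueError(f"need at least {min_len} observations")
    return y, y_hat


def r_squared(y, y_hat) -> float:
    """Generalized coefficient of determination; may be negative."""
    y, y_hat = _paired(y, y_hat, min_len=2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("y is constant; R^2 undefined (zero total sum of squares)")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def adjusted_r_squared(r2: float, N: int, p: int = 4) -> float:
    """Adjust R^2 for sample size N (here: number of experiment sets) and
    predictor count p:  1 - (1 - R^2)(N - 1)/(N - p - 1)."""
    if N <= p + 1:
        raise ValueError(f"need N > p + 1 (got N={N}, p={p})")
    return 1.0 - (1.0 - r2) * (N - 1) / (N - p - 1)


def mean_absolute_error(y, y_hat) -> float:
    """Mean absolute error (1/n) sum |y_i - yhat_i|."""
    y, y_hat = _paired(y, y_hat)
    return float(np.mean(np.abs(y - y_hat)))


def rmse(y, y_hat) -> float:
    """Root mean squared error sqrt((1/n) sum (y_i - yhat_i)^2)."""
    y, y_hat = _paired(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def percent_change(baseline: float, new: float) -> float:
    """Signed percent change of ``new`` relative to ``baseline``:
    100 * (new - baseline) / |baseline|."""
    if baseline == 0:
        raise ValueError("percent change undefined for zero baseline")
    return 100.0 * (new - baseline) / abs(baseline)


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, Welch-Satterthwaite df,
    two-sided p)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both samples have zero variance with different means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def levene_test(a, b) -> tuple[float, float]:
    """Levene test of equal variance with mean centering; returns (W, p)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    dev_a = np.abs(a - a.mean())
    dev_b = np.abs(b - b.mean())
    if np.var(np.concatenate([dev_a, dev_b]), ddof=0) == 0:
        # all absolute deviations identical (e.g. identical constant spread)
        return 0.0, 1.0
    res = stats.levene(a, b, center="mean")
    return float(res.statistic), float(res.pvalue)
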