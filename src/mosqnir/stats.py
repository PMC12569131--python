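"""Shared statistics: adjusted R-squared, robust summaries, allometry.

The nonlinear fitters in :mod:`mosqnir.wing` and :mod:`mosqnir.body` also
use :func:`linearized_ci95` to turn a least-squares Jacobian into 95 %
confidence half-widths (t-quantile times the standard error from the
linearized parameter covariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "adjusted_r2",
    "median_iqr",
    "power_law_fit",
    "PowerLawFit",
    "linearized_ci95",
]


def adjusted_r2(observed, modeled, n_params: int) -> float:
    """Coefficient of determination penalised for model size.

    ``1 - (1 - R^2) (n - 1) / (n - p - 1)`` with ``p`` fitted parameters.
    Raises on degenerate inputs (too few points, zero variance).
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(modeled, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("observed and modeled must be 1-d arrays of equal length")
    n = y.size
    if n <= n_params + 1:
        raise ValueError("need n_obs > n_params + 1")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed values have zero variance")
    sse = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - sse / sst
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles (q25, q75) with linear-interpolation quantiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q25, med, q75 = np.quantile(v, [0.25, 0.5, 0.75])  # type-7 linear
    return float(med), float(q25), float(q75)


@dataclass
class PowerLawFit:
    """Allometric fit y ~ x**gamma (OLS of log y on log x)."""

    gamma: float
    ci95_gamma: tuple[float, float]
    log_intercept: float
    r2_adj: float
    n: int


def power_law_fit(x, y) -> PowerLawFit:
    """Fit the allometric exponent gamma of ``y ~ x**gamma``.

    Ordinary least squares on the log-log scale; the 95 % CI for gamma is
    the standard t-interval of the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive data")
    lx, ly = np.log(x), np.log(y)
    res = sm.OLS(ly, sm.add_constant(lx)).fit()
    lo, hi = res.conf_int(alpha=0.05)[1]
    return PowerLawFit(
        gamma=float(res.params[1]),
        ci95_gamma=(float(lo), float(hi)),
        log_intercept=float(res.params[0]),
        r2_adj=float(res.rsquared_adj),
        n=int(x.size),
    )


def linearized_ci95(jacobian: np.ndarray, residuals: np.ndarray) -> np.ndarray:
    """95 % confidence half-widths from a least-squares solution.

    Uses the linearization covariance ``s^2 (J^T J)^{-1}`` with
    ``s^2 = SSE / (n - p)`` and the two-sided t quantile.  Parameters whose
    variance is not identified (singular J^T J) get infinite half-widths.
    """
    J = np.asarray(jacobian, dtype=float)
    r = np.asarray(residuals, dtype=float)
    n, p = J.shape
    dof = n - p
    if dof <= 0:
        raise ValueError("need more observations than parameters")
    s2 = float(r @ r) / dof
    jtj = J.T @ J
    try:
        cov = np.linalg.inv(jtj) * s2
        var = np.diag(cov).copy()
    except np.linalg.LinAlgError:
        var = np.full(p, np.inf)
    var[var < 0] = np.inf
    tq = sps.t.ppf(0.975, dof)
    return tq * np.sqrt(var)
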