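"""Weighted Deming regression with jackknife standard errors.

Deming regression fits a line treating both variables as measured with
error; ``lam`` is the ratio of the x-error variance to the y-error
variance (1.0 = both equally error-prone, the orthogonal case).  The
weighted variant follows the proportional-error convention: each point is
weighted by 1 / (estimated true value)^2, with the true-value estimate

    xhat_i = (x_i + lam (y_i - a) / b) / (1 + lam / b^2)

recomputed from the current line until the slope stabilises.  Standard
errors come from the delete-one jackknife,

    SE^2 = (n - 1)/n  sum_i (theta_(i) - mean theta_(.))^2,

with 95% confidence limits from Student's t on n - 2 df.  An intercept CL
excluding 0 flags a systematic difference between methods; a slope CL
excluding 1 flags a proportional difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["DemingResult", "weighted_deming", "jackknife_se"]


@dataclass
class DemingResult:
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    cl95_intercept: tuple[float, float]
    cl95_slope: tuple[float, float]
    n: int
    lam: float
    iterations: int
    converged: bool
    systematic: bool   # intercept CL excludes 0
    proportional: bool  # slope CL excludes 1


def _deming_line(x, y, w, lam):
    """Closed-form weighted Deming line for fixed weights."""
    sw = w.sum()
    xb = (w * x).sum() / sw
    yb = (w * y).sum() / sw
    u = (w * (x - xb) ** 2).sum()
    q = (w * (y - yb) ** 2).sum()
    p = (w * (x - xb) * (y - yb)).sum()
    if p == 0:
        # no covariance: vertical/horizontal degenerate; fall back to slope from variances
        slope = np.sqrt(q / (lam * u)) if u > 0 else np.nan
    else:
        slope = ((lam * q - u) + np.sqrt((u - lam * q) ** 2 + 4.0 * lam * p**2)) / (
            2.0 * lam * p
        )
    return yb - slope * xb, slope


def weighted_deming(x, y, lam: float = 1.0, weighted: bool = True,
                    tol: float = 1e-10, max_iter: int = 200):
    """Errors-in-both-variables line fit; returns (intercept, slope).

    With ``weighted=False`` the classical (unweighted) Deming estimate is
    returned, which at ``lam=1`` coincides with orthogonal regression.
    The weighted scheme iterates 1/xhat^2 weights until the slope changes
    by less than ``tol``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal")
    if not (np.isfinite(lam) and lam > 0):
        raise ValueError("lambda must be positive")

    w = np.ones_like(x)
    a, b = _deming_line(x, y, w, lam)
    if not weighted:
        return a, b
    for _ in range(max_iter):
        xhat = (x + lam * (y - a) / b) / (1.0 + lam / b**2)
        w = 1.0 / np.maximum(np.abs(xhat), 1e-8) ** 2
        a_new, b_new = _deming_line(x, y, w, lam)
        if abs(b_new - b) < tol and abs(a_new - a) < tol:
            return a_new, b_new
        a, b = a_new, b_new
    warnings.warn("weighted Deming iteration did not converge", RuntimeWarning)
    return a, b


def jackknife_se(x, y, lam: float = 1.0, weighted: bool = True) -> DemingResult:
    """Full Deming fit with delete-one jackknife SEs and 95% t-based CLs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 4:
        raise ValueError("jackknife needs at least 4 points")
    a, b = weighted_deming(x, y, lam=lam, weighted=weighted)

    reps = []
    dropped = 0
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                reps.append(weighted_deming(x[keep], y[keep], lam=lam, weighted=weighted))
        except ValueError:
            dropped += 1
            warnings.warn(f"degenerate leave-one-out replicate {i} dropped", RuntimeWarning)
        keep[i] = True
    reps = np.asarray(reps)
    m = len(reps)
    mean_rep = reps.mean(axis=0)
    se = np.sqrt((m - 1) / m * ((reps - mean_rep) ** 2).sum(axis=0))
    tcrit = stats.t.ppf(0.975, n - 2)
    cl_a = (a - tcrit * se[0], a + tcrit * se[0])
    cl_b = (b - tcrit * se[1], b + tcrit * se[1])
    return DemingResult(
        intercept=float(a),
        slope=float(b),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        cl95_intercept=(float(cl_a[0]), float(cl_a[1])),
        cl95_slope=(float(cl_b[0]), float(cl_b[1])),
        n=n,
        lam=lam,
        iterations=m,
        converged=dropped == 0,
        systematic=not (cl_a[0] <= 0.0 <= cl_a[1]),
        proportional=not (cl_b[0] <= 1.0 <= cl_b[1]),
    )
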