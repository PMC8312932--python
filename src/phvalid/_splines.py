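"""Natural cubic regression spline basis with analytic derivatives.

Classical truncated-power construction: with knots xi_1 < ... < xi_K the
basis is {1, x, N_1(x), ..., N_{K-2}(x)} where

    N_k(x) = d_k(x) - d_{K-1}(x),
    d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k),

which is linear beyond the boundary knots (the "natural" constraint).
A basis with ``df`` columns beyond the intercept uses K = df + 1 knots
(two boundary + df - 1 interior), matching the convention of R's ns().
"""

from __future__ import annotations

import numpy as np

__all__ = ["NaturalCubicSpline"]


def _pos3(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z**3, 0.0)


def _pos3d(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, 3.0 * z**2, 0.0)


class NaturalCubicSpline:
    """Design/derivative matrices for a natural cubic spline, plus a fit."""

    def __init__(self, knots: np.ndarray):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or len(knots) < 3:
            raise ValueError("need at least 3 distinct knots")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.knots = knots
        self.coef: np.ndarray | None = None

    @classmethod
    def from_quantiles(cls, x: np.ndarray, df: int) -> "NaturalCubicSpline":
        """Boundary knots at min/max of ``x``, interior at even quantiles."""
        if df < 2:
            raise ValueError("df must be >= 2")
        qs = np.linspace(0.0, 1.0, df + 1)
        knots = np.quantile(np.asarray(x, dtype=float), qs)
        # nudge duplicate quantiles apart (ties in small samples)
        for i in range(1, len(knots)):
            if knots[i] <= knots[i - 1]:
                knots[i] = knots[i - 1] + 1e-8
        return cls(knots)

    @property
    def df(self) -> int:
        """Number of basis columns beyond the intercept."""
        return len(self.knots) - 1

    def design(self, x) -> np.ndarray:
        """Basis matrix of shape (len(x), df + 1), first column constant."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        k = self.knots
        K = len(k)
        cols = [np.ones_like(x), x]
        dK1 = (_pos3(x - k[K - 2]) - _pos3(x - k[K - 1])) / (k[K - 1] - k[K - 2])
        for j in range(K - 2):
            dj = (_pos3(x - k[j]) - _pos3(x - k[K - 1])) / (k[K - 1] - k[j])
            cols.append(dj - dK1)
        return np.column_stack(cols)

    def deriv_design(self, x) -> np.ndarray:
        """d/dx of :meth:`design`, same shape."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        k = self.knots
        K = len(k)
        cols = [np.zeros_like(x), np.ones_like(x)]
        dK1 = (_pos3d(x - k[K - 2]) - _pos3d(x - k[K - 1])) / (k[K - 1] - k[K - 2])
        for j in range(K - 2):
            dj = (_pos3d(x - k[j]) - _pos3d(x - k[K - 1])) / (k[K - 1] - k[j])
            cols.append(dj - dK1)
        return np.column_stack(cols)

    # -- fitted-curve interface ------------------------------------------

    def fit(self, x, y, weights=None) -> "NaturalCubicSpline":
        """Least-squares fit of the basis to (x, y); stores coefficients."""
        B = self.design(x)
        y = np.asarray(y, dtype=float)
        if weights is not None:
            w = np.sqrt(np.asarray(weights, dtype=float))
            B = B * w[:, None]
            y = y * w
        self.coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        return self

    def __call__(self, x):
        if self.coef is None:
            raise RuntimeError("spline has no fitted coefficients")
        out = self.design(x) @ self.coef
        return float(out[0]) if np.isscalar(x) else out

    def deriv(self, x):
        if self.coef is None:
            raise RuntimeError("spline has no fitted coefficients")
        out = self.deriv_design(x) @ self.coef
        return float(out[0]) if np.isscalar(x) else out
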