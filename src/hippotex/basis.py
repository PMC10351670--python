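"""Natural cubic spline basis with analytic derivatives.

A natural cubic spline is a piecewise cubic that is constrained to be linear
beyond its boundary knots.  The basis here is the standard truncated-power
construction (as used by R's ``ns``): with knots ``xi_1 < ... < xi_K``
(boundary knots included), define

    d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k)

and take basis functions ``N_1(x) = x`` and
``N_{k+1}(x) = d_k(x) - d_{K-1}(x)`` for ``k = 1 .. K-2``.  This yields
``K - 1`` columns (an intercept is *not* included), each with vanishing second
and third derivatives outside the boundary knots, so a spline with ``df``
degrees of freedom uses ``df + 1`` knots: ``df - 1`` interior knots plus the
two boundary knots.

Analytic first derivatives are exposed because downstream trajectory models
report the slope of the fitted mean curve (sensitivity to change).
"""

from __future__ import annotations

import numpy as np

__all__ = ["NaturalCubicSpline"]


def _pos_cube(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0.0, x, 0.0) ** 3


def _pos_cube_deriv(x: np.ndarray) -> np.ndarray:
    return 3.0 * np.where(x > 0.0, x, 0.0) ** 2


class NaturalCubicSpline:
    """Natural cubic spline basis defined by a fixed knot sequence.

    Parameters
    ----------
    knots : array-like
        Strictly increasing knot sequence *including* the two boundary knots.
        A sequence of ``m`` knots gives a basis with ``m - 1`` columns
        (degrees of freedom, intercept excluded).
    """

    def __init__(self, knots):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or knots.size < 2:
            raise ValueError("need at least two knots (the boundary knots)")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.knots = knots

    # ------------------------------------------------------------------
    @classmethod
    def from_data(cls, x, df: int, boundary_quantiles=(0.0, 1.0)) -> "NaturalCubicSpline":
        """Place ``df - 1`` interior knots at quantiles of ``x``.

        Boundary knots sit at the given quantiles of ``x`` (defaults to the
        data range); interior knots at equally spaced quantiles in between.
        """
        if df < 1:
            raise ValueError("df must be >= 1")
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        lo_q, hi_q = boundary_quantiles
        lo, hi = np.quantile(x, [lo_q, hi_q])
        if not hi > lo:
            raise ValueError("degenerate data range: cannot place knots")
        inner_q = np.linspace(0.0, 1.0, df + 1)[1:-1]
        inner = np.quantile(x[(x >= lo) & (x <= hi)], inner_q) if df > 1 else np.array([])
        knots = np.unique(np.concatenate([[lo], inner, [hi]]))
        if knots.size < df + 1:
            # duplicate quantiles (heavily tied data): fall back to an even grid
            knots = np.linspace(lo, hi, df + 1)
        return cls(knots)

    # ------------------------------------------------------------------
    @property
    def df(self) -> int:
        return self.knots.size - 1

    def _d(self, x: np.ndarray, k: int, deriv: bool) -> np.ndarray:
        xi = self.knots
        last = xi[-1]
        f = _pos_cube_deriv if deriv else _pos_cube
        return (f(x - xi[k]) - f(x - last)) / (last - xi[k])

    def design(self, x) -> np.ndarray:
        """Evaluate the basis; returns an ``(n, df)`` array."""
        x = np.asarray(x, dtype=float)
        cols = [x]
        if self.knots.size > 2:
            d_last = self._d(x, self.knots.size - 2, deriv=False)
            for k in range(self.knots.size - 2):
                cols.append(self._d(x, k, deriv=False) - d_last)
        return np.column_stack(cols)

    def derivative(self, x) -> np.ndarray:
        """First derivative of each basis column; ``(n, df)`` array."""
        x = np.asarray(x, dtype=float)
        cols = [np.ones_like(x)]
        if self.knots.size > 2:
            d_last = self._d(x, self.knots.size - 2, deriv=True)
            for k in range(self.knots.size - 2):
                cols.append(self._d(x, k, deriv=True) - d_last)
        return np.column_stack(cols)

    def __repr__(self) -> str:  # pragma: no cover
        return f"NaturalCubicSpline(df={self.df}, knots={np.round(self.knots, 3)})"
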