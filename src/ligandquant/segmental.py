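"""Linear and segmental (broken-stick) regression for quench titrations.

A biotin-4-fluorescein titration against a fixed amount of Strep-Tactin
shows near-flat fluorescence while binding sites absorb (and quench) the
dye, then a sharp linear rise once sites saturate and free dye accumulates.
The saturation point is the breakpoint ``x0`` of a continuous two-segment
linear model:

    Y1 = intercept1 + slope1 * X                    (X < x0)
    Y2 = Y1(x0) + slope2 * (X - x0)                 (X >= x0)

Given x0 the model is linear in (intercept1, slope1, slope2), so the fit
profiles x0 over candidate breakpoints (midpoints between adjacent distinct
x), solves each conditional linear problem in closed form, and polishes the
best candidate with a bounded scalar optimizer.  This is globally reliable
where a generic 4-parameter optimizer can stall in local minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .datasets import DegenerateDataError

__all__ = ["LinearFitResults", "fit_linear", "SegmentalRegression",
           "SegmentalRegressionResults"]


@dataclass
class LinearFitResults:
    """Ordinary least-squares line fit ``Y = M*X + B``."""

    slope: float
    intercept: float
    sse: float
    nobs: int

    def predict(self, x):
        return self.slope * np.asarray(x, float) + self.intercept

    def summary(self) -> str:
        return (f"Linear fit (n={self.nobs})\n"
                f"  slope     M = {self.slope:.6g}\n"
                f"  intercept B = {self.intercept:.6g}\n"
                f"  sse         = {self.sse:.6g}")


def fit_linear(x, y) -> LinearFitResults:
    """Ordinary least-squares straight line, used for buffer-only controls.

    Raises
    ------
    DegenerateDataError
        If fewer than two distinct x values are supplied.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.unique(x).size < 2:
        raise DegenerateDataError("linear fit needs >= 2 distinct x values")
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return LinearFitResults(slope=float(coef[0]), intercept=float(coef[1]),
                            sse=float(resid @ resid), nobs=x.size)


def _segmental_design(x: np.ndarray, x0: float) -> np.ndarray:
    # Y = intercept1 + slope1*min(x, x0) + slope2*max(x - x0, 0):
    # continuity at x0 holds by construction.
    return np.column_stack([
        np.ones_like(x),
        np.minimum(x, x0),
        np.maximum(x - x0, 0.0),
    ])


def _conditional_fit(x, y, x0):
    """Closed-form linear sub-fit at a fixed breakpoint; returns (coef, sse)."""
    A = _segmental_design(x, x0)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float(resid @ resid)


@dataclass
class SegmentalRegressionResults:
    """Continuous two-segment linear fit with its breakpoint.

    ``x0`` is the concentration at which the segments intersect — the
    titration's saturation inflection.  ``bse`` holds standard errors in
    the same order as ``params``; ``x0_se`` may be NaN when the local
    curvature is singular (e.g. exactly linear data).
    """

    intercept1: float
    slope1: float
    slope2: float
    x0: float
    sse: float
    nobs: int
    converged: bool
    x0_se: float = float("nan")
    bse: np.ndarray = None  # (intercept1, slope1, slope2, x0)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.intercept1, self.slope1, self.slope2, self.x0])

    def predict(self, x):
        x = np.asarray(x, float)
        y_at_x0 = self.intercept1 + self.slope1 * self.x0
        y1 = self.intercept1 + self.slope1 * x
        y2 = y_at_x0 + self.slope2 * (x - self.x0)
        return np.where(x < self.x0, y1, y2)

    def summary(self) -> str:
        lines = [f"Segmental linear regression (n={self.nobs}, "
                 f"converged={self.converged})"]
        names = ["intercept1", "slope1", "slope2", "x0"]
        ses = self.bse if self.bse is not None else [float("nan")] * 4
        for name, val, se in zip(names, self.params, ses):
            lines.append(f"  {name:<10s} = {val:.6g}  (se {se:.3g})")
        lines.append(f"  sse        = {self.sse:.6g}")
        return "\n".join(lines)


class SegmentalRegression:
    """Broken-stick model for a quench titration.

    Parameters
    ----------
    x, y : array-like
        Concentration (molar) and background-corrected fluorescence (AU).
        Needs at least five points with at least two distinct x values on
        each side of any admissible breakpoint; the breakpoint is
        constrained strictly between the 2nd and (n-1)th sorted distinct x.
    """

    def __init__(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        order = np.argsort(x, kind="stable")
        self.x, self.y = x[order], y[order]
        self._xu = np.unique(self.x)
        if self.x.size < 5 or self._xu.size < 5:
            raise DegenerateDataError(
                "segmental fit needs >= 5 points with >= 5 distinct x")

    @classmethod
    def from_series(cls, series) -> "SegmentalRegression":
        return cls(series.x, series.y)

    def _candidates(self) -> np.ndarray:
        # Midpoints between adjacent distinct x such that >= 2 distinct x
        # fall on each side: breakpoints between xu[1] and xu[-2].
        xu = self._xu
        mids = (xu[:-1] + xu[1:]) / 2.0
        return mids[(mids > xu[1]) & (mids < xu[-2])]

    def fit(self, polish: bool = True) -> SegmentalRegressionResults:
        """Profile the breakpoint over candidates, then locally polish.

        Ties between equal-sse candidates resolve to the smallest x0
        (the conservative saturation estimate).
        """
        cands = self._candidates()
        if cands.size == 0:
            raise DegenerateDataError("no admissible interior breakpoint")
        sses = np.array([_conditional_fit(self.x, self.y, c)[1] for c in cands])
        # smallest x0 among near-ties (relative tolerance on sse)
        tol = 1e-9 * max(sses.min(), np.finfo(float).tiny)
        best_idx = int(np.flatnonzero(sses <= sses.min() + tol)[0])
        x0 = float(cands[best_idx])
        converged = True

        if polish:
            lo = self._xu[1] if best_idx == 0 else float(cands[best_idx - 1])
            hi = self._xu[-2] if best_idx == len(cands) - 1 else float(cands[best_idx + 1])
            if hi > lo:
                res = minimize_scalar(
                    lambda b: _conditional_fit(self.x, self.y, b)[1],
                    bounds=(lo, hi), method="bounded",
                    options={"xatol": 1e-12 * (self._xu[-1] - self._xu[0])})
                converged = bool(res.success)
                if res.fun <= sses[best_idx] + tol:
                    x0 = float(res.x)

        coef, sse = _conditional_fit(self.x, self.y, x0)
        bse = self._standard_errors(coef, x0, sse)
        return SegmentalRegressionResults(
            intercept1=float(coef[0]), slope1=float(coef[1]),
            slope2=float(coef[2]), x0=x0, sse=sse,
            nobs=self.x.size, converged=converged,
            x0_se=float(bse[3]), bse=bse)

    def _standard_errors(self, coef, x0, sse) -> np.ndarray:
        """Asymptotic SEs from the Jacobian of (intercept1, slope1, slope2, x0)."""
        n = self.x.size
        dof = n - 4
        if dof <= 0:
            return np.full(4, np.nan)
        a0, a1, a2 = coef  # intercept1, slope1, slope2
        right = self.x >= x0
        J = np.empty((n, 4))
        J[:, 0] = 1.0
        J[:, 1] = np.minimum(self.x, x0)
        J[:, 2] = np.maximum(self.x - x0, 0.0)
        # right branch: Y = a0 + a1*x0 + a2*(x - x0), so dY/dx0 = a1 - a2
        J[:, 3] = np.where(right, a1 - a2, 0.0)
        try:
            cov = np.linalg.inv(J.T @ J) * (sse / dof)
        except np.linalg.LinAlgError:
            return np.full(4, np.nan)
        var = np.diag(cov).copy()
        var[var < 0] = np.nan
        return np.sqrt(var)


def grid_search_breakpoint(x, y, candidates=None):
    """Exhaustive breakpoint search used as an independent oracle in tests.

    Evaluates the conditional linear fit at every candidate (default: all
    midpoints between adjacent distinct x) and returns ``(x0, sse)`` of the
    best, ties to the smallest x0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if candidates is None:
        xu = np.unique(x)
        mids = (xu[:-1] + xu[1:]) / 2.0
        candidates = mids[(mids > xu[1]) & (mids < xu[-2])]
    best = (None, np.inf)
    for c in sorted(candidates):
        _, sse = _conditional_fit(x, y, c)
        if sse < best[1]:
            best = (float(c), sse)
    return best
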