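"""One-site saturation binding, absolute calibration, and surface decay.

Coupling-protein binding to anchor cells follows the one-site isotherm

    Y = Bmax * X / (KD_app + X)

where Y is the population MFI or gMFI and ``KD_app`` is the concentration
giving half-maximal cell binding (an operational, avidity-laden quantity,
not a solution K_D).  A relative curve becomes an absolute calibration by
replacing the fitted Bmax with the quench-derived ligand count at the
saturating concentration; half-saturation is preserved.  Ligand loss from
the cell surface over time is fitted with a single exponential
``Y = (Y0 - Plateau) * exp(-K * t) + Plateau`` whose half-life is ln(2)/K.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .datasets import DegenerateDataError
from .quench import LigandCount

__all__ = ["SaturationBinding", "SaturationFitResults", "CalibrationCurve",
           "ExponentialDecay", "DecayFitResults", "half_life"]


def one_site(x, bmax, kd):
    x = np.asarray(x, float)
    return bmax * x / (kd + x)


@dataclass
class SaturationFitResults:
    """Fitted one-site binding isotherm."""

    bmax: float
    kd_app: float
    bmax_se: float
    kd_se: float
    sse: float
    nobs: int
    converged: bool
    y_statistic: str = "median"
    spans_kd: bool = True

    def predict(self, x):
        return one_site(x, self.bmax, self.kd_app)

    def summary(self) -> str:
        return (f"One-site saturation binding (n={self.nobs}, "
                f"y={self.y_statistic}, converged={self.converged})\n"
                f"  Bmax   = {self.bmax:.6g}  (se {self.bmax_se:.3g})\n"
                f"  KD_app = {self.kd_app:.6g} M  (se {self.kd_se:.3g})\n"
                f"  sse    = {self.sse:.6g}")


class SaturationBinding:
    """One-site specific binding model for a cell-binding titration.

    Parameters
    ----------
    x, y : array-like
        Coupling-protein concentration (molar) and background-corrected
        MFI/gMFI.  At least four points; a warning is issued when the
        concentrations do not bracket the apparent KD.
    y_statistic : {"median", "geometric_mean"}
        Which population summary y was extracted with (metadata only).
    weighting : {"relative", "none"}
        Relative (proportional) least squares by default: MFI noise scales
        with the signal, so residuals are divided by the model mean (with a
        floor of 5% of Bmax near zero).  ``"none"`` gives plain least
        squares.
    """

    def __init__(self, x, y, y_statistic: str = "median",
                 weighting: str = "relative"):
        self.x = np.asarray(x, float)
        self.y = np.asarray(y, float)
        if self.x.size < 4:
            raise DegenerateDataError("saturation fit needs >= 4 points")
        if np.all(self.y == 0):
            raise DegenerateDataError("all-zero y: nothing to fit")
        if y_statistic not in ("median", "geometric_mean"):
            raise ValueError("y_statistic must be median or geometric_mean")
        if weighting not in ("relative", "none"):
            raise ValueError("weighting must be 'relative' or 'none'")
        self.y_statistic = y_statistic
        self.weighting = weighting

    @classmethod
    def from_series(cls, series, y_statistic: str = "median",
                    weighting: str = "relative") -> "SaturationBinding":
        return cls(series.x, series.y, y_statistic=y_statistic,
                   weighting=weighting)

    def _start(self):
        bmax0 = float(self.y.max())
        above = self.x[self.y > bmax0 / 2]
        kd0 = float(above[0]) if above.size else float(np.median(self.x[self.x > 0]))
        return max(bmax0, np.finfo(float).tiny), max(kd0, np.finfo(float).tiny)

    def fit(self) -> SaturationFitResults:
        p0 = self._start()
        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if self.weighting == "relative":
                    # iteratively reweighted: two passes of curve_fit with
                    # sigma proportional to the current model mean
                    popt = np.asarray(p0, float)
                    for _ in range(2):
                        mean = one_site(self.x, *popt)
                        sigma = np.maximum(np.abs(mean), 0.05 * popt[0])
                        popt, pcov = curve_fit(
                            one_site, self.x, self.y, p0=popt, sigma=sigma,
                            absolute_sigma=False,
                            bounds=([0, 0], [np.inf, np.inf]), maxfev=20000)
                else:
                    popt, pcov = curve_fit(one_site, self.x, self.y, p0=p0,
                                           bounds=([0, 0], [np.inf, np.inf]),
                                           maxfev=20000)
        except RuntimeError:
            popt, pcov = np.array(p0), np.full((2, 2), np.nan)
            converged = False
        resid = self.y - one_site(self.x, *popt)
        se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan] * 2
        spans = bool(self.x.min() < popt[1] < self.x.max())
        if not spans:
            warnings.warn("concentrations do not bracket the apparent KD; "
                          "estimate may be poorly identified", stacklevel=2)
        return SaturationFitResults(
            bmax=float(popt[0]), kd_app=float(popt[1]),
            bmax_se=float(se[0]), kd_se=float(se[1]),
            sse=float(resid @ resid), nobs=self.x.size,
            converged=converged, y_statistic=self.y_statistic,
            spans_kd=spans)


@dataclass
class CalibrationCurve:
    """Absolute ligand-number calibration curve.

    The quench-derived count at saturating coupling-protein concentration
    stands in for Bmax; ``KD_app`` is carried over unchanged, so the
    relative and absolute curves share their half-saturation concentration.
    """

    bmax_absolute: float
    kd_app: float
    source_count: Optional[LigandCount] = None
    fitted_range: tuple = (0.0, float("inf"))

    @classmethod
    def from_fit(cls, fit: SaturationFitResults,
                 count_at_saturation: LigandCount,
                 fitted_range: tuple = None) -> "CalibrationCurve":
        """Substitute an absolute count for the fitted (relative) Bmax."""
        if count_at_saturation.ligands_per_cell <= 0:
            raise ValueError("saturating ligand count must be positive")
        return cls(bmax_absolute=count_at_saturation.ligands_per_cell,
                   kd_app=fit.kd_app, source_count=count_at_saturation,
                   fitted_range=fitted_range or (0.0, float("inf")))

    def ligands_at(self, conc: float) -> tuple[float, bool]:
        """Interpolated ligands per cell at a coupling-protein concentration.

        Returns ``(count, extrapolated)``; ``extrapolated`` is True when the
        requested concentration lies outside the fitted data range.
        """
        if conc < 0:
            raise ValueError(f"concentration must be non-negative, got {conc}")
        extrapolated = not (self.fitted_range[0] <= conc <= self.fitted_range[1])
        return float(one_site(conc, self.bmax_absolute, self.kd_app)), extrapolated


def exp_decay(t, y0, plateau, k):
    t = np.asarray(t, float)
    return (y0 - plateau) * np.exp(-k * t) + plateau


@dataclass
class DecayFitResults:
    """Single-exponential surface-decay fit (time in minutes)."""

    y0: float
    plateau: float
    k: float
    k_se: float
    sse: float
    nobs: int
    converged: bool

    @property
    def half_life(self) -> float:
        return half_life(self.k)

    def predict(self, t):
        return exp_decay(t, self.y0, self.plateau, self.k)

    def summary(self) -> str:
        return (f"Exponential decay (n={self.nobs}, converged={self.converged})\n"
                f"  Y0        = {self.y0:.6g}\n"
                f"  Plateau   = {self.plateau:.6g}\n"
                f"  K         = {self.k:.6g} /min  (se {self.k_se:.3g})\n"
                f"  half-life = {self.half_life:.6g} min\n"
                f"  sse       = {self.sse:.6g}")


class ExponentialDecay:
    """Surface down-regulation model: normalized MFI vs time in minutes.

    y is expected normalized so that the t = 0 value is 1; fitting starts
    at t = 0 by default (set ``from_peak=True`` to drop the initial rise
    sometimes seen immediately after ligand reconstitution).
    """

    def __init__(self, t, y, from_peak: bool = False):
        t = np.asarray(t, float)
        y = np.asarray(y, float)
        if from_peak:
            i = int(np.argmax(y))
            t, y = t[i:] - t[i], y[i:]
        if t.size < 4:
            raise DegenerateDataError("decay fit needs >= 4 points")
        self.t, self.y = t, y

    @classmethod
    def from_series(cls, series, from_peak: bool = False) -> "ExponentialDecay":
        return cls(series.x, series.y, from_peak=from_peak)

    def fit(self) -> DecayFitResults:
        span = self.t.max() - self.t.min()
        k0 = math.log(2) / (span / 2) if span > 0 else 1.0
        p0 = (float(self.y.max()), float(self.y.min()), k0)
        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(exp_decay, self.t, self.y, p0=p0,
                                       bounds=([-np.inf, -np.inf, 0],
                                               [np.inf, np.inf, np.inf]),
                                       maxfev=20000)
        except RuntimeError:
            popt, pcov = np.array(p0), np.full((3, 3), np.nan)
            converged = False
        if popt[2] <= 1e-12 or popt[0] <= popt[1]:
            warnings.warn("data do not decay (K ~ 0 or Y0 <= Plateau)",
                          stacklevel=2)
            converged = False
        resid = self.y - exp_decay(self.t, *popt)
        k_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else float("nan")
        return DecayFitResults(
            y0=float(popt[0]), plateau=float(popt[1]), k=float(popt[2]),
            k_se=k_se, sse=float(resid @ resid), nobs=self.t.size,
            converged=converged)


def half_life(k: float) -> float:
    """Half-life ln(2)/K in minutes for a rate constant K (per minute)."""
    if k <= 0:
        raise ValueError(f"rate constant must be positive, got {k}")
    return math.log(2) / k
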