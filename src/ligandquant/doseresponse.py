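"""Dose-response (EC50) analysis of receptor-activation readouts.

Cellular readouts — secreted IL-8 (pg/mL), %eGFP-positive cells, or CD69
MFI — measured against the number of ligands per cell are fitted with the
four-parameter log-logistic model on a log10 dose axis:

    Y = Bottom + (Top - Bottom) / (1 + 10**((log10(EC50) - log10(X)) * HillSlope))

EC50 is the ligand number per cell giving a half-maximal response.  The
fixed-slope variant (HillSlope = 1) is used for CAR CD69 analyses.
Zero-dose wells cannot sit on a log axis; they inform Bottom directly
(the model's X -> 0 limit) and are otherwise excluded.

Helpers implement the surrounding bookkeeping: background subtraction
with the below-detection-to-zero rule, %positive gating against negative
controls, normalisation to the per-dataset maximum, EC50 aggregation
across experiments, and fold-change reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from scipy.optimize import least_squares

from .datasets import DegenerateDataError
from .affinity import _covariance

__all__ = ["log_logistic", "DoseResponseExperiment", "LogLogistic",
           "DoseResponseResults", "EC50Summary", "subtract_background",
           "gate_percent_positive", "normalize_to_max", "summarize_ec50",
           "fold_change"]


def log_logistic(x, bottom, top, log10_ec50, hillslope=1.0):
    """Four-parameter log-logistic response at doses ``x`` (> 0)."""
    x = np.asarray(x, float)
    with np.errstate(divide="ignore"):
        expo = (log10_ec50 - np.log10(x)) * hillslope
    return bottom + (top - bottom) / (1.0 + np.power(10.0, expo))


def subtract_background(samples, controls, detection_limit: float = 0.0):
    """Background-correct readouts against matched negative controls.

    Values at or below the detection limit are set to 0 *before*
    subtraction (the convention for below-detection ELISA wells); controls
    may be a scalar (pooled) or a vector matched one-to-one.  Negative
    corrected values are retained, not clipped, and flagged.

    Returns
    -------
    corrected : ndarray
    negative_flags : ndarray of bool
        True where the corrected value is negative.
    """
    samples = np.asarray(samples, float)
    if controls is None:
        raise ValueError("negative controls are required for background correction")
    controls = np.asarray(controls, float)
    if controls.ndim > 0 and controls.shape != samples.shape:
        raise ValueError("controls must be scalar or match samples in shape")
    samples = np.where(samples <= detection_limit, 0.0, samples)
    corrected = samples - controls
    return corrected, corrected < 0


def gate_percent_positive(sample_events, control_events,
                          quantile: float = 0.99) -> float:
    """Percent positive above a negative-control gate, background-corrected.

    The gate is the given quantile of the control distribution (default
    0.99; 1.0 uses the control maximum).  The control's own percentage
    above the gate is subtracted and the result floored at zero.
    """
    sample_events = np.asarray(sample_events, float)
    control_events = np.asarray(control_events, float)
    if sample_events.size == 0 or control_events.size == 0:
        raise ValueError("event sets must be non-empty")
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    threshold = float(np.quantile(control_events, quantile))
    pct_sample = 100.0 * np.mean(sample_events > threshold)
    pct_control = 100.0 * np.mean(control_events > threshold)
    return max(0.0, pct_sample - pct_control)


@dataclass
class DoseResponseExperiment:
    """One dose-response experiment after background correction.

    ``doses`` are ligand counts per cell or relative ligand levels (AU);
    ``responses`` are background-corrected readouts in ``response_unit``.
    Zero doses are allowed (they constrain Bottom); fitted points need
    positive doses.
    """

    doses: np.ndarray
    responses: np.ndarray
    response_unit: str = "pg_per_mL"
    dose_type: str = "ligands_per_cell"
    experiment_id: str = "experiment"
    normalized: bool = False

    def __post_init__(self):
        self.doses = np.asarray(self.doses, float)
        self.responses = np.asarray(self.responses, float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must match in shape")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")
        if np.any(self.doses < 0):
            raise ValueError("doses must be non-negative")

    @property
    def n_distinct_doses(self) -> int:
        return int(np.unique(self.doses[self.doses > 0]).size)


def normalize_to_max(experiment: DoseResponseExperiment) -> DoseResponseExperiment:
    """Scale responses so the dataset maximum is exactly 1."""
    m = experiment.responses.max()
    if m <= 0:
        raise ValueError("maximal corrected response must be positive to normalize")
    return DoseResponseExperiment(
        doses=experiment.doses.copy(),
        responses=experiment.responses / m,
        response_unit="normalized",
        dose_type=experiment.dose_type,
        experiment_id=experiment.experiment_id,
        normalized=True)


@dataclass
class DoseResponseResults:
    """Fitted log-logistic dose-response curve."""

    bottom: float
    top: float
    log10_ec50: float
    hillslope: float
    ec50_se: float
    sse: float
    nobs: int
    converged: bool
    hill_fixed: bool
    normalized: bool = False
    ec50_in_range: bool = True
    experiment_id: str = "experiment"

    @property
    def ec50(self) -> float:
        return float(np.power(10.0, np.float64(self.log10_ec50)))

    def predict(self, x):
        return log_logistic(x, self.bottom, self.top, self.log10_ec50,
                            self.hillslope)

    def summary(self) -> str:
        slope = ("1 (fixed)" if self.hill_fixed
                 else f"{self.hillslope:.4g}")
        flags = []
        if not self.converged:
            flags.append("NOT CONVERGED")
        if not self.ec50_in_range:
            flags.append("EC50 outside 10x data range")
        tag = ("  [" + "; ".join(flags) + "]") if flags else ""
        return (f"Log-logistic dose-response fit "
                f"({self.experiment_id}, n={self.nobs}){tag}\n"
                f"  Bottom    = {self.bottom:.6g}\n"
                f"  Top       = {self.top:.6g}\n"
                f"  EC50      = {self.ec50:.6g}  (se {self.ec50_se:.3g})\n"
                f"  HillSlope = {slope}\n"
                f"  sse       = {self.sse:.6g}")


class LogLogistic:
    """Four-parameter log-logistic dose-response model.

    Parameters
    ----------
    experiment : DoseResponseExperiment
    fix_hillslope : bool, default False
        Fit with HillSlope fixed at 1 (the unit-slope variant).
    weighting : {"relative", "none"}
        Relative (proportional) least squares by default — readout noise
        scales with the signal over dose ranges spanning orders of
        magnitude; residuals are divided by |model mean| floored at 5% of
        the fitted response span.  ``"none"`` gives plain least squares.
    """

    def __init__(self, experiment: DoseResponseExperiment,
                 fix_hillslope: bool = False, weighting: str = "relative"):
        if weighting not in ("relative", "none"):
            raise ValueError("weighting must be 'relative' or 'none'")
        self.weighting = weighting
        self.experiment = experiment
        self.fix_hillslope = fix_hillslope
        pos = experiment.doses > 0
        self._x = experiment.doses[pos]
        self._y = experiment.responses[pos]
        self._y0 = experiment.responses[~pos]  # zero-dose wells -> Bottom
        if self._x.size < 3:
            raise DegenerateDataError("dose-response fit needs >= 3 positive doses")
        if experiment.n_distinct_doses < 5:
            warnings.warn("fewer than 5 distinct doses; the transition may "
                          "be poorly constrained", stacklevel=2)

    @classmethod
    def from_experiment(cls, experiment, slope: str = "variable",
                        weighting: str = "relative") -> "LogLogistic":
        return cls(experiment, fix_hillslope=(slope == "fixed"),
                   weighting=weighting)

    def _start(self):
        bottom0 = float(min(self._y.min(), self._y0.min() if self._y0.size else np.inf))
        top0 = float(self._y.max())
        half = (bottom0 + top0) / 2
        i = int(np.argmin(np.abs(self._y - half)))
        return bottom0, top0, float(np.log10(self._x[i]))

    def fit(self) -> DoseResponseResults:
        bottom0, top0, le0 = self._start()
        free_slope = not self.fix_hillslope
        theta0 = [bottom0, top0, le0] + ([1.0] if free_slope else [])

        def resid(theta):
            bottom, top, le = theta[:3]
            slope = theta[3] if free_slope else 1.0
            pred = log_logistic(self._x, bottom, top, le, slope)
            r = pred - self._y
            if self._y0.size:
                pred = np.concatenate([pred, np.full(self._y0.size, bottom)])
                r = np.concatenate([r, bottom - self._y0])
            if self.weighting == "relative":
                floor = 0.05 * max(abs(top - bottom), 1e-12)
                r = r / np.maximum(np.abs(pred), floor)
            return r

        # bound log10(EC50) loosely around the dose range so a flat or
        # degenerate dataset cannot push it to +/- infinity
        le_lo = np.log10(self._x.min()) - 6.0
        le_hi = np.log10(self._x.max()) + 6.0
        lo = [-np.inf, -np.inf, le_lo] + ([-50.0] if free_slope else [])
        hi = [np.inf, np.inf, le_hi] + ([50.0] if free_slope else [])
        theta0[2] = np.clip(theta0[2], le_lo, le_hi)
        res = least_squares(resid, theta0, method="trf", bounds=(lo, hi),
                            x_scale="jac", max_nfev=20000)
        bottom, top, le = res.x[:3]
        slope = float(res.x[3]) if free_slope else 1.0
        cov = _covariance(res)
        le_se = np.sqrt(cov[2, 2]) if np.isfinite(cov[2, 2]) else np.nan
        ec50 = 10.0 ** le
        ec50_se = float(ec50 * np.log(10) * le_se)
        in_range = bool(self._x.min() / 10 < ec50 < self._x.max() * 10)
        if not in_range:
            warnings.warn(f"EC50 {ec50:.3g} lies outside 10x the dose range",
                          stacklevel=2)
        raw = log_logistic(self._x, bottom, top, le, slope) - self._y
        if self._y0.size:
            raw = np.concatenate([raw, bottom - self._y0])
        return DoseResponseResults(
            bottom=float(bottom), top=float(top), log10_ec50=float(le),
            hillslope=slope, ec50_se=ec50_se, sse=float(raw @ raw),
            nobs=self._x.size + self._y0.size,
            converged=bool(res.success), hill_fixed=self.fix_hillslope,
            normalized=self.experiment.normalized,
            ec50_in_range=in_range,
            experiment_id=self.experiment.experiment_id)


@dataclass
class EC50Summary:
    """Mean and sample SD of per-experiment EC50s."""

    mean: float
    sd: float
    n: int
    ec50s: list = field(default_factory=list)

    def summary(self) -> str:
        sd = f"{self.sd:.6g}" if self.n > 1 else "n/a (single experiment)"
        return (f"EC50 across {self.n} experiment(s)\n"
                f"  mean = {self.mean:.6g}\n"
                f"  sd   = {sd}")


def summarize_ec50(fits: Sequence[DoseResponseResults]) -> EC50Summary:
    """Aggregate converged per-experiment EC50s into mean +/- sample SD."""
    good = [f for f in fits if f.converged]
    if not good:
        raise ValueError("no converged dose-response fits to summarize")
    ec50s = [f.ec50 for f in good]
    sd = float(np.std(ec50s, ddof=1)) if len(ec50s) > 1 else 0.0
    return EC50Summary(mean=float(np.mean(ec50s)), sd=sd,
                       n=len(ec50s), ec50s=ec50s)


def fold_change(a: float, b: float) -> tuple[float, int]:
    """Ratio ``a / b`` and its nearest-integer fold."""
    if b == 0:
        raise ValueError("zero denominator in fold change")
    if a <= 0 or b <= 0:
        raise ValueError("fold change requires positive values")
    ratio = a / b
    return ratio, round(ratio)
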