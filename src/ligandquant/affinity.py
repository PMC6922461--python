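"""Equilibrium affinity estimation with a shared-K_D global constraint.

SPR equilibrium binding of a tagged analyte over immobilised coupling
protein is described by the Hill isotherm

    Y = Bmax * X**h / (KD**h + X**h)

with Y the specific binding (RU), X the analyte concentration (molar),
and h the Hill slope.  Repeats on different chips or immobilisation
levels have different Bmax (and, empirically, slightly different h), but
one underlying K_D — so the global fit shares K_D across all series while
leaving Bmax and h per-series, and reports the mean Hill slope with its
SEM across series.

All parameters are optimised on the natural-log scale for positivity and
conditioning, then reported on the natural scale with delta-method SEs.

Because SPR series span orders of magnitude in both concentration and
response, and measurement error scales with the signal, the fits default
to relative (proportional) least squares — residuals divided by the
model mean — which is the maximum-likelihood objective under
constant-CV noise and markedly stabilises K_D when the Hill slope is
shallow.  Plain unweighted least squares is available via
``weighting="none"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .datasets import DegenerateDataError, EquilibriumSeries

__all__ = ["hill", "HillBinding", "HillFitResults",
           "SharedAffinityModel", "GlobalAffinityResults"]


def hill(x, bmax, kd, h):
    x = np.asarray(x, float)
    xh = np.power(x, h)
    return bmax * xh / (np.power(kd, h) + xh)


def _covariance(res) -> np.ndarray:
    """Gauss-Newton covariance of a least_squares solution."""
    m, p = res.jac.shape
    dof = m - p
    if dof <= 0:
        return np.full((p, p), np.nan)
    s2 = 2.0 * res.cost / dof
    try:
        jtj_inv = np.linalg.inv(res.jac.T @ res.jac)
    except np.linalg.LinAlgError:
        return np.full((p, p), np.nan)
    return s2 * jtj_inv


@dataclass
class HillFitResults:
    bmax: float
    kd: float
    h: float
    kd_se: float
    sse: float
    nobs: int
    converged: bool

    def predict(self, x):
        return hill(x, self.bmax, self.kd, self.h)

    def summary(self) -> str:
        return (f"Hill equilibrium binding (n={self.nobs}, "
                f"converged={self.converged})\n"
                f"  Bmax = {self.bmax:.6g} RU\n"
                f"  KD   = {self.kd:.6g} M  (se {self.kd_se:.3g})\n"
                f"  h    = {self.h:.6g}\n"
                f"  sse  = {self.sse:.6g}")


def _start_values(x, y):
    bmax0 = max(float(np.max(y)), np.finfo(float).tiny)
    above = x[y > bmax0 / 2]
    kd0 = float(above[0]) if above.size else float(np.exp(np.mean(np.log(x))))
    return bmax0, kd0


def _weighted(resid_raw, mean, weighting):
    if weighting == "none":
        return resid_raw
    return resid_raw / np.maximum(np.abs(mean), 1e-12)


class HillBinding:
    """Single-series Hill equilibrium fit; ``fix_h=1`` reduces to one-site."""

    def __init__(self, x, y, fix_h: float | None = None,
                 weighting: str = "relative"):
        self.x = np.asarray(x, float)
        self.y = np.asarray(y, float)
        if self.x.size < 4:
            raise DegenerateDataError("equilibrium fit needs >= 4 points")
        if np.any(self.x <= 0):
            raise ValueError("analyte concentrations must be positive")
        if self.x.max() / self.x.min() < 10:
            warnings.warn("concentrations span less than one order of "
                          "magnitude; KD may be poorly identified", stacklevel=2)
        if weighting not in ("relative", "none"):
            raise ValueError("weighting must be 'relative' or 'none'")
        self.fix_h = fix_h
        self.weighting = weighting

    @classmethod
    def from_series(cls, series: EquilibriumSeries, fix_h=None,
                    weighting: str = "relative") -> "HillBinding":
        return cls(series.x, series.y, fix_h=fix_h, weighting=weighting)

    def fit(self) -> HillFitResults:
        bmax0, kd0 = _start_values(self.x, self.y)
        free_h = self.fix_h is None
        theta0 = np.log([bmax0, kd0] + ([1.0] if free_h else []))

        def resid(theta):
            bmax, kd = np.exp(theta[:2])
            h = np.exp(theta[2]) if free_h else self.fix_h
            mean = hill(self.x, bmax, kd, h)
            return _weighted(mean - self.y, mean, self.weighting)

        res = least_squares(resid, theta0, method="lm", max_nfev=20000)
        bmax, kd = np.exp(res.x[:2])
        h = float(np.exp(res.x[2])) if free_h else float(self.fix_h)
        cov = _covariance(res)
        kd_se = float(kd * np.sqrt(cov[1, 1])) if np.isfinite(cov[1, 1]) else float("nan")
        raw = hill(self.x, bmax, kd, h) - self.y
        return HillFitResults(
            bmax=float(bmax), kd=float(kd), h=h, kd_se=kd_se,
            sse=float(raw @ raw), nobs=self.x.size,
            converged=bool(res.success))


@dataclass
class GlobalAffinityResults:
    """Shared-K_D global fit across equilibrium binding repeats."""

    kd: float
    kd_se: float
    bmax: np.ndarray          # per series
    h: np.ndarray             # per series
    mean_h: float
    sem_h: float
    sse: float
    n_series: int
    nobs: int
    converged: bool
    series_ids: list = field(default_factory=list)
    excluded: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"Global equilibrium affinity fit "
                 f"({self.n_series} series, n={self.nobs}, "
                 f"converged={self.converged})",
                 f"  shared KD = {self.kd:.6g} M  (se {self.kd_se:.3g})",
                 f"  mean Hill slope = {self.mean_h:.3g}  (SEM {self.sem_h:.2g})",
                 f"  sse = {self.sse:.6g}"]
        for sid, b, h in zip(self.series_ids, self.bmax, self.h):
            lines.append(f"    {sid}: Bmax = {b:.6g} RU, h = {h:.4g}")
        if self.excluded:
            lines.append(f"  excluded series: {self.excluded}")
        return "\n".join(lines)


class SharedAffinityModel:
    """Simultaneous fit of several equilibrium series with one shared K_D.

    Parameters
    ----------
    series_list : list of EquilibriumSeries (or objects with .x/.y)
    share_h : bool, default False
        Share the Hill slope across series as well (sensitivity analysis);
        by default h is per-series and summarised as mean +/- SEM.
    """

    def __init__(self, series_list, share_h: bool = False,
                 weighting: str = "relative"):
        if weighting not in ("relative", "none"):
            raise ValueError("weighting must be 'relative' or 'none'")
        self.weighting = weighting
        if not series_list:
            raise DegenerateDataError("need at least one equilibrium series")
        self.series, self.excluded = [], []
        for i, s in enumerate(series_list):
            sid = getattr(s, "series_id", f"series_{i}")
            try:
                x = np.asarray(s.x, float)
                if x.size < 4 or np.any(x <= 0):
                    raise DegenerateDataError("degenerate series")
                self.series.append(s)
            except (DegenerateDataError, ValueError) as exc:
                warnings.warn(f"excluding series {sid}: {exc}", stacklevel=2)
                self.excluded.append(sid)
        if not self.series:
            raise DegenerateDataError("all series degenerate")
        self.share_h = share_h

    def fit(self) -> GlobalAffinityResults:
        ns = len(self.series)
        starts = [_start_values(s.x, s.y) for s in self.series]
        kd0 = float(np.exp(np.mean([np.log(kd) for _, kd in starts])))
        # theta = [log kd, log bmax_1..ns, log h (1 or ns)]
        nh = 1 if self.share_h else ns
        theta0 = np.concatenate([[np.log(kd0)],
                                 np.log([b for b, _ in starts]),
                                 np.zeros(nh)])

        def unpack(theta):
            kd = np.exp(theta[0])
            bmax = np.exp(theta[1:1 + ns])
            h = np.exp(theta[1 + ns:])
            if self.share_h:
                h = np.repeat(h, ns)
            return kd, bmax, h

        def resid(theta):
            kd, bmax, h = unpack(theta)
            return np.concatenate([
                _weighted(hill(s.x, bmax[i], kd, h[i]) - s.y,
                          hill(s.x, bmax[i], kd, h[i]), self.weighting)
                for i, s in enumerate(self.series)])

        res = least_squares(resid, theta0, method="lm", max_nfev=50000)
        kd, bmax, h = unpack(res.x)
        cov = _covariance(res)
        kd_se = float(kd * np.sqrt(cov[0, 0])) if np.isfinite(cov[0, 0]) else float("nan")
        mean_h = float(np.mean(h))
        sem_h = float(np.std(h, ddof=1) / np.sqrt(ns)) if ns > 1 else 0.0
        nobs = sum(s.x.size for s in self.series)
        raw = np.concatenate([hill(s.x, bmax[i], kd, h[i]) - s.y
                              for i, s in enumerate(self.series)])
        return GlobalAffinityResults(
            kd=float(kd), kd_se=kd_se, bmax=bmax, h=h,
            mean_h=mean_h, sem_h=sem_h, sse=float(raw @ raw),
            n_series=ns, nobs=nobs, converged=bool(res.success),
            series_ids=[getattr(s, "series_id", f"series_{i}")
                        for i, s in enumerate(self.series)],
            excluded=self.excluded)
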