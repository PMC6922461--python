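"""Bead-calibrated absolute molecule counts from flow-cytometry MFI.

Quantitation beads carry known antibody-binding capacities (or
fluorophore equivalents); running them alongside stained cells yields a
standard curve mapping MFI to molecules.  The curve is a least-squares
line on a configurable scale (linear by default, log-log optional).
Sample MFIs are background-subtracted, inverted through the curve, and
divided by the antibody's degree of labelling (fluorophores per
molecule) to give molecules per cell.  Samples brighter than the top
bead are extrapolated — allowed, flagged, and bounded at 10x the top
bead capacity.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .datasets import DegenerateDataError

__all__ = ["BeadStandard", "BeadStandardResults", "CountEstimate",
           "counts_from_mfi"]


@dataclass
class BeadStandardResults:
    """Fitted bead standard curve (capacity as a function of MFI)."""

    slope: float
    intercept: float
    r_squared: float
    scale: str                      # "linear" | "loglog"
    mfi_range: tuple
    capacity_range: tuple
    nobs: int

    def capacity_at(self, mfi):
        """Predicted binding capacity for an MFI on this standard."""
        mfi = np.asarray(mfi, float)
        if self.scale == "linear":
            return self.slope * mfi + self.intercept
        return 10.0 ** (self.slope * np.log10(mfi) + self.intercept)

    def mfi_at(self, capacity):
        """Inverse of :meth:`capacity_at` (predicted MFI for a capacity)."""
        capacity = np.asarray(capacity, float)
        if self.scale == "linear":
            return (capacity - self.intercept) / self.slope
        return 10.0 ** ((np.log10(capacity) - self.intercept) / self.slope)

    def summary(self) -> str:
        return (f"Bead standard curve ({self.scale} scale, "
                f"{self.nobs} bead populations)\n"
                f"  slope     = {self.slope:.6g}\n"
                f"  intercept = {self.intercept:.6g}\n"
                f"  R^2       = {self.r_squared:.6f}")


class BeadStandard:
    """Standard-curve model from quantitation-bead populations.

    Parameters
    ----------
    mfi, capacity : array-like
        Per-population MFI and known binding capacity, both positive;
        at least three populations.  Capacities that are not monotone
        increasing with MFI trigger a warning.
    scale : {"linear", "loglog"}
        Regression scale; linear is the manufacturer convention for the
        bead kits emulated here.
    """

    def __init__(self, mfi, capacity, scale: str = "linear"):
        mfi = np.asarray(mfi, float)
        capacity = np.asarray(capacity, float)
        if mfi.size < 3:
            raise DegenerateDataError("bead standard needs >= 3 populations")
        if np.any(mfi <= 0) or np.any(capacity <= 0):
            raise ValueError("bead MFIs and capacities must be positive")
        order = np.argsort(mfi)
        self.mfi, self.capacity = mfi[order], capacity[order]
        if np.any(np.diff(self.capacity) <= 0):
            warnings.warn("bead capacities are not strictly increasing with "
                          "MFI; the standard curve may be unreliable",
                          stacklevel=2)
        if scale not in ("linear", "loglog"):
            raise ValueError("scale must be 'linear' or 'loglog'")
        self.scale = scale

    def fit(self) -> BeadStandardResults:
        if self.scale == "linear":
            u, v = self.mfi, self.capacity
        else:
            u, v = np.log10(self.mfi), np.log10(self.capacity)
        slope, intercept = np.polyfit(u, v, 1)
        pred = slope * u + intercept
        ss_res = float(np.sum((v - pred) ** 2))
        ss_tot = float(np.sum((v - v.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return BeadStandardResults(
            slope=float(slope), intercept=float(intercept), r_squared=r2,
            scale=self.scale,
            mfi_range=(float(self.mfi.min()), float(self.mfi.max())),
            capacity_range=(float(self.capacity.min()),
                            float(self.capacity.max())),
            nobs=self.mfi.size)


@dataclass
class CountEstimate:
    """Molecules per cell derived from a bead standard curve."""

    molecules_per_cell: float
    extrapolated: bool
    below_background: bool
    degree_of_labelling: float
    corrected_mfi: float
    sample_id: str = "sample"

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "molecules_per_cell": self.molecules_per_cell,
            "extrapolated": self.extrapolated,
            "below_background": self.below_background,
            "degree_of_labelling": self.degree_of_labelling,
            "corrected_mfi": self.corrected_mfi,
        }


def counts_from_mfi(standard: BeadStandardResults, sample_mfi: float,
                    background_mfi: float = 0.0,
                    degree_of_labelling: float = 1.0,
                    sample_id: str = "sample",
                    extrapolation_limit: float = 10.0) -> CountEstimate:
    """Convert a sample MFI to molecules per cell via the bead standard.

    Background MFI is subtracted first; a non-positive corrected MFI
    yields a count of 0 with ``below_background`` set.  Corrected MFIs
    outside the bead range are extrapolated and flagged; estimates beyond
    ``extrapolation_limit`` times the top bead capacity raise an error.
    """
    if degree_of_labelling <= 0:
        raise ValueError("degree of labelling must be positive")
    corrected = sample_mfi - background_mfi
    if corrected <= 0:
        return CountEstimate(0.0, extrapolated=False, below_background=True,
                             degree_of_labelling=degree_of_labelling,
                             corrected_mfi=corrected, sample_id=sample_id)
    capacity = float(standard.capacity_at(corrected))
    capacity = max(capacity, 0.0)
    extrapolated = not (standard.mfi_range[0] <= corrected <= standard.mfi_range[1])
    if capacity > extrapolation_limit * standard.capacity_range[1]:
        raise ValueError(
            f"estimate {capacity:.3g} exceeds {extrapolation_limit:g}x the top "
            f"bead capacity {standard.capacity_range[1]:.3g}; not reportable")
    return CountEstimate(capacity / degree_of_labelling,
                         extrapolated=extrapolated, below_background=False,
                         degree_of_labelling=degree_of_labelling,
                         corrected_mfi=corrected, sample_id=sample_id)
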