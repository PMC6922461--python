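"""Typed containers for titration-style measurement series.

Every fitting model in this package consumes a :class:`TitrationSeries`:
an ordered set of (x, y) measurements with a declared role (what kind of
assay produced it) and unit metadata.  Construction sorts by x and
validates the invariants each role requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Recognised series roles.
ROLES = ("quench", "binding", "spr", "decay", "dose_response", "bead")


class DegenerateDataError(ValueError):
    """Raised when a series cannot support the requested fit."""


@dataclass
class TitrationSeries:
    """Ordered (x, y) measurements from one titration or time course.

    Parameters
    ----------
    x : array-like
        Independent variable.  Concentration in molar for quench / binding /
        spr series, time in minutes for decay series, ligand count or
        relative level for dose-response series.
    y : array-like
        Measured signal (background-corrected fluorescence, MFI/gMFI,
        SPR response units, or cellular readout), finite.
    role : str
        One of ``quench | binding | spr | decay | dose_response | bead``.
    series_id : str
        Identifier used in grouped fits and reports.
    x_unit, y_unit : str
        Units after normalisation (``M``, ``min``, ``AU``, ``RU`` ...).
    replicate : array-like, optional
        Per-point replicate labels.
    meta : dict
        Free-form provenance (cell count, sample volume, sites per ligand,
        seed of a simulation, ...).
    """

    x: np.ndarray
    y: np.ndarray
    role: str = "quench"
    series_id: str = "series"
    x_unit: str = "M"
    y_unit: str = "AU"
    replicate: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.role not in ROLES:
            raise ValueError(f"unknown series role {self.role!r}")
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite values")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("x contains non-finite values")
        if np.any(self.x < 0):
            raise ValueError("x must be non-negative")
        order = np.argsort(self.x, kind="stable")
        self.x = self.x[order]
        self.y = self.y[order]
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)[order]

    def __len__(self) -> int:
        return self.x.size

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, role: str, series_id: str = "series",
                       x: str = "x_value", y: str = "y_value", **kwargs) -> "TitrationSeries":
        return cls(df[x].to_numpy(float), df[y].to_numpy(float), role=role,
                   series_id=series_id, **kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "series_id": self.series_id,
            "role": self.role,
            "x_value": self.x,
            "x_unit": self.x_unit,
            "y_value": self.y,
            "y_unit": self.y_unit,
        })
        if self.replicate is not None:
            df["replicate"] = self.replicate
        else:
            # number repeated x values so (series_id, x, replicate) is unique
            df["replicate"] = df.groupby("x_value").cumcount() + 1
        return df


@dataclass
class QuenchTitration(TitrationSeries):
    """Biotin-4-fluorescein quench titration.

    x is dye concentration (molar); y is background-corrected fluorescence
    (AU; negative corrected values are retained, not clipped).  The context
    is either a soluble tetramer titration (``tetramer_conc`` in molar) or a
    cell suspension (``cells``, ``volume_l`` and ``sites_per_ligand``).
    """

    tetramer_conc: Optional[float] = None
    cells: Optional[float] = None
    volume_l: Optional[float] = None
    sites_per_ligand: Optional[int] = None

    def __post_init__(self):
        self.role = "quench"
        super().__post_init__()
        if len(self) < 5:
            raise DegenerateDataError(
                f"quench titration needs >= 5 points, got {len(self)}")
        for name in ("tetramer_conc", "cells", "volume_l", "sites_per_ligand"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass
class EquilibriumSeries(TitrationSeries):
    """One SPR equilibrium binding series (analyte concentration vs RU)."""

    immobilization_level: Optional[str] = None

    def __post_init__(self):
        self.role = "spr"
        super().__post_init__()
        if len(self) < 4:
            raise DegenerateDataError(
                f"equilibrium series needs >= 4 points, got {len(self)}")
        if np.any(self.x <= 0):
            raise ValueError("analyte concentrations must be positive")

    @property
    def spans_decade(self) -> bool:
        """True when concentrations cover at least one order of magnitude."""
        return self.x.max() / self.x.min() >= 10.0
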