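"""Absolute ligand counting from quench-titration inflection points.

Once the saturation inflection ``x0`` (molar) of a biotin-4-fluorescein
titration is known, complete binding of the dye converts it directly into
molecule counts: for a soluble tetramer titration, sites per tetramer;
for a cell suspension, average ligands per cell

    L = x0 * V * N_A / (C * B)

with sample volume V (litres), cell count C and B biotin-binding sites
per ligand (3 for the trivalent coupling protein, 1 for monovalent).
Surface density follows by dividing by the spherical-cell surface area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import AVOGADRO, DEFAULT_CELL_SURFACE_AREA_UM2

__all__ = ["LigandCount", "sites_per_tetramer", "ligands_per_cell",
           "sphere_surface_area", "density_per_um2"]


@dataclass
class LigandCount:
    """Average ligands per cell with full provenance.

    The count assumes complete binding of biotin-4-fluorescein to the
    coupling protein (recorded in ``assumptions``); uncertainty in x0 is
    not propagated into L (``x0_se_propagated`` is always False).
    """

    ligands_per_cell: float
    x0: float
    volume_l: float
    cells: float
    sites_per_ligand: float
    density_per_um2: float
    surface_area_um2: float
    avogadro: float = AVOGADRO
    assumptions: tuple = ("complete_binding",)
    x0_se_propagated: bool = False

    def to_dict(self) -> dict:
        return {
            "ligands_per_cell": self.ligands_per_cell,
            "x0_molar": self.x0,
            "volume_l": self.volume_l,
            "cells": self.cells,
            "sites_per_ligand": self.sites_per_ligand,
            "density_per_um2": self.density_per_um2,
            "surface_area_um2": self.surface_area_um2,
            "avogadro": self.avogadro,
            "assumptions": list(self.assumptions),
            "x0_se_propagated": self.x0_se_propagated,
        }


def sites_per_tetramer(x0: float, tetramer_conc: float) -> float:
    """Biotin-binding sites per tetramer from a soluble-protein titration.

    Assumes complete binding, so the dye concentration at saturation equals
    the total binding-site concentration; dividing by the tetramer
    concentration added gives sites per tetramer.
    """
    if tetramer_conc <= 0:
        raise ValueError(f"tetramer_conc must be positive, got {tetramer_conc}")
    return x0 / tetramer_conc


def ligands_per_cell(x0: float, volume_l: float, cells: float,
                     sites_per_ligand: float,
                     surface_area_um2: float = DEFAULT_CELL_SURFACE_AREA_UM2,
                     avogadro: float = AVOGADRO) -> LigandCount:
    """Convert a cell-suspension saturation inflection to ligands per cell.

    Parameters
    ----------
    x0 : float
        Saturation concentration of biotin-4-fluorescein (molar).
    volume_l : float
        Sample volume in litres.
    cells : float
        Number of cells in the sample.
    sites_per_ligand : float
        Biotin-binding sites per ligand; 3 for trivalent, 1 for monovalent
        coupling protein (other values accepted but unusual).
    surface_area_um2 : float, default 700
        Cell surface area used for the density estimate.
    avogadro : float
        Configurable for testing only.
    """
    if x0 < 0:
        raise ValueError(f"x0 must be non-negative, got {x0}")
    for name, v in (("volume_l", volume_l), ("cells", cells),
                    ("sites_per_ligand", sites_per_ligand),
                    ("surface_area_um2", surface_area_um2)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    L = x0 * volume_l * avogadro / (cells * sites_per_ligand)
    return LigandCount(
        ligands_per_cell=L, x0=x0, volume_l=volume_l, cells=cells,
        sites_per_ligand=sites_per_ligand,
        density_per_um2=L / surface_area_um2,
        surface_area_um2=surface_area_um2, avogadro=avogadro)


def sphere_surface_area(diameter_um: float) -> tuple[float, float]:
    """Surface area of a spherical cell, in um^2.

    Returns the exact value ``pi * d**2`` and the value rounded to the
    nearest hundred (the convention used for the 15-um CHO cell, 700 um^2).
    """
    if diameter_um <= 0:
        raise ValueError(f"diameter must be positive, got {diameter_um}")
    area = math.pi * diameter_um ** 2
    return area, round(area / 100.0) * 100.0


def density_per_um2(ligand_count: float,
                    surface_area_um2: float = DEFAULT_CELL_SURFACE_AREA_UM2) -> float:
    """Ligands per square micrometre for a given per-cell count."""
    if surface_area_um2 <= 0:
        raise ValueError(f"surface_area must be positive, got {surface_area_um2}")
    if ligand_count < 0:
        raise ValueError(f"ligand count must be non-negative, got {ligand_count}")
    return ligand_count / surface_area_um2
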