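"""Synthetic instrument data with known ground truth.

Every assay in the pipeline has a generator here drawing from the same
generative model the corresponding fit assumes, plus multiplicative
Gaussian noise:

* quench titrations — continuous two-segment line with an inflection at
  binding-site saturation (2% CV default, typical plate-reader precision);
* cell populations — lognormal per-cell ligand copy numbers whose mean
  follows the one-site isotherm in coupling-protein concentration, with
  fluorescence proportional to copies plus autofluorescence;
* SPR equilibrium series — Hill isotherm with shared K_D and per-series
  Bmax and Hill slope (5% CV default);
* decay time courses — single exponential normalized to t = 0 (3% CV);
* dose-response experiments — log-logistic response plus background,
  with optional below-detection censoring to zero (10% CV default,
  typical cell-assay variability).

Identical seeds and parameters give bit-identical output.  These data
reproduce curve shapes and noise magnitudes, not instrument artefacts
(carry-over, edge effects, spectral spillover), so recovery tests bound
statistical, not systematic, error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .datasets import (TitrationSeries, QuenchTitration, EquilibriumSeries)
from .doseresponse import DoseResponseExperiment, log_logistic
from .saturation import one_site, exp_decay
from .affinity import hill

__all__ = ["GroundTruth", "gen_quench_titration", "gen_cell_population",
           "gen_binding_titration", "gen_equilibrium_series",
           "gen_decay_series", "gen_dose_response_experiment",
           "CellPopulation"]


@dataclass
class GroundTruth:
    """True parameters behind one synthetic scenario.

    Only the fields relevant to a given generator need to be set; the
    seed is recorded in every emitted dataset's metadata.
    """

    scenario: str = "default"
    seed: int = 0
    # quench (two-segment) truth
    intercept1: float = 50.0
    slope1: float = 2e8       # AU per molar, quenched regime
    slope2: float = 4e9       # AU per molar, free-dye regime
    x0: float = 1.5e-7        # molar, saturation inflection
    # saturation-binding truth
    bmax: float = 1000.0
    kd: float = 1e-7          # molar
    hill_h: float = 1.0
    # per-cell copy-number spread (arithmetic CV of the lognormal)
    copy_cv: float = 0.5
    autofluorescence: float = 50.0
    fluorescence_per_copy: float = 1e-3
    # decay truth
    y0: float = 1.0
    plateau: float = 0.1
    k: float = np.log(2) / 820.0   # per minute
    # dose-response truth
    bottom: float = 0.0
    top: float = 1000.0
    ec50: float = 2e5
    hillslope: float = 1.2
    background: float = 20.0
    detection_limit: float = 0.0
    # noise (Gaussian CV unless stated otherwise)
    noise_cv: float = 0.02

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(truth_or_seed) -> np.random.Generator:
    seed = getattr(truth_or_seed, "seed", truth_or_seed)
    return np.random.default_rng(seed)


def _apply_cv_noise(mean: np.ndarray, cv: float, rng, floor_sd: float = 0.0):
    """Multiplicative Gaussian noise; optional additive floor for values
    near zero (sd = max(cv*|mean|, floor_sd))."""
    if cv == 0 and floor_sd == 0:
        return mean.copy()
    sd = np.maximum(cv * np.abs(mean), floor_sd)
    return mean + rng.normal(0.0, 1.0, size=mean.shape) * sd


def gen_quench_titration(truth: GroundTruth, n_points: int = 12,
                         noise_cv: Optional[float] = None,
                         x_max: Optional[float] = None,
                         **context) -> QuenchTitration:
    """Two-segment quench titration with the inflection strictly interior.

    x runs linearly from 0 to ``x_max`` (default 3 * x0); ``context``
    passes through tetramer_conc / cells / volume_l / sites_per_ligand.
    """
    noise_cv = truth.noise_cv if noise_cv is None else noise_cv
    x_max = 3.0 * truth.x0 if x_max is None else x_max
    if not 0 < truth.x0 < x_max:
        raise ValueError("the inflection x0 must lie inside the x range")
    rng = _rng(truth)
    x = np.linspace(0.0, x_max, n_points)
    y_at_x0 = truth.intercept1 + truth.slope1 * truth.x0
    mean = np.where(x < truth.x0,
                    truth.intercept1 + truth.slope1 * x,
                    y_at_x0 + truth.slope2 * (x - truth.x0))
    scale = max(abs(y_at_x0), 1.0)
    y = _apply_cv_noise(mean, noise_cv, rng, floor_sd=noise_cv * 0.1 * scale)
    return QuenchTitration(x, y, series_id=truth.scenario,
                           meta={"seed": truth.seed, "truth": truth.to_dict()},
                           **context)


@dataclass
class CellPopulation:
    """Per-cell copy numbers and fluorescence events at one concentration."""

    concentration: float
    copies: np.ndarray
    fluorescence: np.ndarray
    true_mean: float
    seed: int

    @property
    def median_fluorescence(self) -> float:
        return float(np.median(self.fluorescence))

    @property
    def gmfi(self) -> float:
        f = self.fluorescence[self.fluorescence > 0]
        return float(np.exp(np.mean(np.log(f))))


def gen_cell_population(truth: GroundTruth, n_cells: int,
                        concentration: float) -> CellPopulation:
    """Lognormal per-cell ligand copies at one coupling concentration.

    The arithmetic mean copy number follows the one-site isotherm
    ``bmax * c / (kd + c)``; the lognormal's sigma is set from the
    arithmetic CV (``copy_cv``), so the median is mean / sqrt(1 + cv^2).
    Event fluorescence is proportional to copies plus autofluorescence.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = _rng(truth)
    mean = float(one_site(concentration, truth.bmax, truth.kd))
    if truth.copy_cv > 0 and mean > 0:
        sigma2 = np.log1p(truth.copy_cv ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        copies = rng.lognormal(mu, np.sqrt(sigma2), size=n_cells)
    else:
        copies = np.full(n_cells, mean)
    fluor = truth.fluorescence_per_copy * copies + truth.autofluorescence
    return CellPopulation(concentration=concentration, copies=copies,
                          fluorescence=fluor, true_mean=mean, seed=truth.seed)


def gen_binding_titration(truth: GroundTruth, concentrations: Sequence[float],
                          n_cells: int = 2000,
                          statistic: str = "median") -> TitrationSeries:
    """Background-corrected MFI titration built from cell populations.

    One population is simulated per concentration (sub-seeded
    deterministically); the summary statistic minus the autofluorescence
    background gives the corrected y used by the saturation fit.
    """
    ys = []
    for i, c in enumerate(concentrations):
        sub = GroundTruth(**{**truth.to_dict(),
                             "seed": (truth.seed * 1000 + i) % (2 ** 31)})
        pop = gen_cell_population(sub, n_cells, c)
        stat = pop.median_fluorescence if statistic == "median" else pop.gmfi
        ys.append(stat - truth.autofluorescence)
    return TitrationSeries(np.asarray(concentrations, float), np.asarray(ys),
                           role="binding", series_id=truth.scenario,
                           meta={"seed": truth.seed, "statistic": statistic,
                                 "truth": truth.to_dict()})


def gen_equilibrium_series(truth: GroundTruth, n_series: int = 11,
                           n_conc: int = 12, noise_cv: float = 0.05,
                           replicates: int = 3,
                           bmax_spread: float = 0.3,
                           h_spread: float = 0.05,
                           conc_span: tuple = (1e-3, 50.0)) -> list:
    """SPR repeats sharing K_D, with per-series Bmax and Hill slope.

    ``replicates`` injections at each of ``n_conc`` log-spaced
    concentrations spanning ``conc_span`` times K_D — a serial-dilution
    range bounded above by what a soluble analyte stock permits (~50x a
    micromolar K_D).  Per-series Bmax is jittered lognormally
    (immobilisation-level differences) and h normally around the truth.
    """
    rng = _rng(truth)
    x = np.repeat(np.geomspace(conc_span[0] * truth.kd,
                               conc_span[1] * truth.kd, n_conc), replicates)
    out = []
    for i in range(n_series):
        bmax_i = truth.bmax * rng.lognormal(0.0, bmax_spread)
        h_i = max(truth.hill_h + rng.normal(0.0, h_spread), 0.05)
        mean = hill(x, bmax_i, truth.kd, h_i)
        y = _apply_cv_noise(mean, noise_cv, rng)
        out.append(EquilibriumSeries(
            x, y, series_id=f"{truth.scenario}_rep{i + 1}",
            y_unit="RU",
            meta={"seed": truth.seed, "bmax_true": bmax_i, "h_true": h_i,
                  "kd_true": truth.kd}))
    return out


def gen_decay_series(truth: GroundTruth, timepoints: Sequence[float] = None,
                     noise_cv: float = 0.03) -> TitrationSeries:
    """Normalized surface-decay time course (t = 0 value exactly 1)."""
    rng = _rng(truth)
    if timepoints is None:
        # cover ~3 half-lives
        timepoints = np.linspace(0.0, 3.0 * np.log(2) / truth.k, 13)
    t = np.asarray(timepoints, float)
    mean = exp_decay(t, truth.y0, truth.plateau, truth.k)
    y = _apply_cv_noise(mean, noise_cv, rng)
    if t[0] == 0.0:
        y[0] = mean[0]          # normalisation reference point
        y = y / y[0]
    return TitrationSeries(t, y, role="decay", series_id=truth.scenario,
                           x_unit="min", y_unit="normalized",
                           meta={"seed": truth.seed, "truth": truth.to_dict()})


def gen_dose_response_experiment(truth: GroundTruth,
                                 doses: Sequence[float] = None,
                                 replicates: int = 2,
                                 noise_cv: float = 0.10,
                                 readout_unit: str = "pg_per_mL",
                                 include_zero_dose: bool = True
                                 ) -> DoseResponseExperiment:
    """Log-logistic receptor-activation experiment with background.

    Responses are the model mean plus background with multiplicative
    noise, then background-corrected against simulated negative controls
    (background alone with the same noise).  Values at or below the
    detection limit are censored to zero before correction, matching the
    handling of below-detection ELISA wells.
    """
    rng = _rng(truth)
    if doses is None:
        doses = np.geomspace(truth.ec50 / 100, truth.ec50 * 100, 8)
    doses = np.asarray(doses, float)
    all_doses = np.repeat(doses, replicates)
    if include_zero_dose:
        all_doses = np.concatenate([np.zeros(replicates), all_doses])
    mean = np.where(all_doses > 0,
                    log_logistic(all_doses, truth.bottom, truth.top,
                                 np.log10(truth.ec50), truth.hillslope),
                    truth.bottom)
    raw = _apply_cv_noise(mean + truth.background, noise_cv, rng)
    controls = _apply_cv_noise(np.full_like(raw, truth.background),
                               noise_cv, rng)
    raw = np.where(raw <= truth.detection_limit, 0.0, raw)
    corrected = raw - controls
    return DoseResponseExperiment(
        doses=all_doses, responses=corrected, response_unit=readout_unit,
        experiment_id=f"{truth.scenario}_seed{truth.seed}")
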