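"""Config-driven end-to-end analysis run.

A :class:`RunConfig` names the input CSVs by role plus the analysis
switches the underlying assays leave open (population statistic, gate
quantile, Hill-slope mode, bead-curve scale).  :func:`run_pipeline`
executes quench fitting -> absolute ligand counting -> binding
calibration -> dose-response fitting, logging every default and flag so
a run is auditable, and writes one JSON document per stage plus a
combined summary into the output directory.  Reruns with identical
inputs and seed produce identical JSON.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as lio
from .datasets import DegenerateDataError
from .segmental import SegmentalRegression
from .quench import ligands_per_cell
from .saturation import SaturationBinding, CalibrationCurve
from .doseresponse import (DoseResponseExperiment, LogLogistic,
                           normalize_to_max, subtract_background,
                           summarize_ec50)

logger = logging.getLogger("ligandquant.pipeline")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Inputs and switches for one end-to-end run."""

    quench_csv: Optional[str] = None
    binding_csv: Optional[str] = None
    dose_response_csv: Optional[str] = None
    out_dir: str = "ligandquant_run"
    # quench -> count context
    cells: float = 1e6
    volume_l: float = 1e-4
    sites_per_ligand: int = 3
    # switches (defaults logged because the assays leave them open)
    y_statistic: str = "median"
    slope_mode: str = "variable"        # variable | fixed
    normalize: bool = False
    gate_quantile: float = 0.99
    bead_scale: str = "linear"
    seed: Optional[int] = None

    def validate(self, required=("quench_csv", "binding_csv", "dose_response_csv")):
        for role in required:
            p = getattr(self, role)
            if p is None:
                raise PipelineError(f"config error: missing input role {role!r}")
            if not Path(p).exists():
                raise PipelineError(f"config error: {role} file {p!r} not found")


def run_pipeline(config: RunConfig) -> Path:
    """Run quench -> counting -> calibration -> dose-response; return out dir.

    Each stage failure aborts with a :class:`PipelineError` naming the
    stage.  The saturating concentration used for calibration (highest
    concentration on the fitted plateau, within 5% of Bmax) is recorded.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run config: %s", asdict(config))
    summary = {"config": asdict(config)}

    # --- stage 1: quench titration -> saturation inflection -> count
    try:
        quench_series = lio.read_titration_csv(config.quench_csv, role="quench")
        if not quench_series:
            raise DegenerateDataError("no quench series in input")
        sfit = SegmentalRegression.from_series(quench_series[0]).fit()
        count = ligands_per_cell(sfit.x0, config.volume_l, config.cells,
                                 config.sites_per_ligand)
    except Exception as exc:
        raise PipelineError(f"stage quench-fit failed: {exc}") from exc
    logger.info("quench inflection x0=%.4g M -> %.4g ligands/cell",
                sfit.x0, count.ligands_per_cell)
    summary["quench"] = {"x0_molar": sfit.x0, "x0_se": sfit.x0_se,
                         "sse": sfit.sse, "converged": sfit.converged,
                         "ligand_count": count.to_dict()}

    # --- stage 2: binding titration -> relative curve -> absolute calibration
    try:
        binding_series = lio.read_titration_csv(config.binding_csv, role="binding")
        if not binding_series:
            raise DegenerateDataError("no binding series in input")
        bseries = binding_series[0]
        bfit = SaturationBinding.from_series(
            bseries, y_statistic=config.y_statistic).fit()
        plateau = bseries.x[bfit.predict(bseries.x) >= 0.95 * bfit.bmax]
        saturating_conc = float(plateau[0]) if plateau.size else float(bseries.x.max())
        curve = CalibrationCurve.from_fit(
            bfit, count, fitted_range=(float(bseries.x.min()),
                                       float(bseries.x.max())))
    except Exception as exc:
        raise PipelineError(f"stage binding-calibrate failed: {exc}") from exc
    logger.info("calibration: Bmax=%.4g ligands/cell at KD_app=%.4g M "
                "(saturating conc %.4g M)", curve.bmax_absolute,
                curve.kd_app, saturating_conc)
    summary["calibration"] = {
        "bmax_relative_au": bfit.bmax, "kd_app_molar": bfit.kd_app,
        "kd_app_se": bfit.kd_se, "converged": bfit.converged,
        "y_statistic": config.y_statistic,
        "saturating_concentration_molar": saturating_conc,
        "bmax_absolute": curve.bmax_absolute}

    # --- stage 3: dose-response fits
    try:
        experiments = lio.read_dose_response_csv(config.dose_response_csv)
        fits = []
        for eid, grp in experiments.items():
            ctrl = grp.loc[grp["is_control"], "response_value"]
            samp = grp.loc[~grp["is_control"]]
            if ctrl.empty:
                raise DegenerateDataError(f"experiment {eid!r} has no controls")
            corrected, neg = subtract_background(
                samp["response_value"].to_numpy(float), float(ctrl.mean()))
            exp = DoseResponseExperiment(
                doses=samp["dose_value"].to_numpy(float),
                responses=corrected,
                response_unit=str(samp["response_unit"].iloc[0]),
                dose_type=str(samp["dose_type"].iloc[0]),
                experiment_id=eid)
            if config.normalize:
                exp = normalize_to_max(exp)
            fit = LogLogistic.from_experiment(exp, slope=config.slope_mode).fit()
            logger.info("dose-response %s: EC50=%.4g (%d negative corrected "
                        "responses retained)", eid, fit.ec50, int(neg.sum()))
            fits.append(fit)
        ec50s = summarize_ec50(fits)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage dose-response failed: {exc}") from exc
    summary["dose_response"] = {
        "fits": [{"experiment_id": f.experiment_id, "bottom": f.bottom,
                  "top": f.top, "ec50": f.ec50, "ec50_se": f.ec50_se,
                  "hillslope": f.hillslope, "hill_fixed": f.hill_fixed,
                  "normalized": f.normalized, "sse": f.sse, "n": f.nobs,
                  "converged": f.converged, "ec50_in_range": f.ec50_in_range}
                 for f in fits],
        "ec50_mean": ec50s.mean, "ec50_sd": ec50s.sd, "n_experiments": ec50s.n}

    lio.write_results_json(summary, out / "summary.json", seed=config.seed)
    logger.info("run complete: %s", out / "summary.json")
    return out
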