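# ligandquant

Absolute quantification of engineered cell-surface ligands and
dose-response analysis of the immunoreceptors they activate.

## The problem

Generic-ligand systems couple a soluble Strep-Tactin/streptavidin-based
"ligand head" to a membrane anchor (via SpyTag–SpyCatcher) so that any
Twin-Strep-tagged receptor — TCRs, Siglecs, SIRPs, NKp30, nanobody CARs —
can be stimulated by a cell-presented ligand whose surface density is set
by titration.  Interpreting those experiments needs a quantitative chain
that turns raw instrument readouts into absolute molecule numbers:

1. **Quench titration → absolute counts.**  Biotin-4-fluorescein is
   quenched while it binds free Strep-Tactin sites; past saturation,
   fluorescence rises sharply.  The titration is a continuous two-segment
   line whose breakpoint `X0` marks site saturation:

   `Y = intercept1 + slope1·X` for `X < X0`, continuing with `slope2`
   beyond.  Assuming complete dye binding, `X0` converts to binding sites
   per tetramer (`X0 / [tetramer]`) or, for a cell suspension, to the
   mean ligand count per cell `L = X0·V·N_A / (C·B)` with sample volume
   `V`, cell count `C` and `B` biotin sites per ligand (3 trivalent,
   1 monovalent).  Densities divide by a 700 µm² spherical-cell surface.
2. **Binding curve → calibration.**  Coupling-protein binding to anchor
   cells follows `Y = Bmax·X/(K_D + X)`.  Substituting the quench-derived
   count at saturation for the fitted (relative) `Bmax` yields a curve
   that interpolates ligands/cell at any coupling concentration.
3. **Equilibrium affinity.**  SPR series are fitted globally with the
   Hill isotherm `Y = Bmax·X^h/(K_D^h + X^h)`, sharing one `K_D` across
   repeats while `Bmax` and `h` stay per-series (mean `h` ± SEM reported).
4. **Surface stability.**  Ligand loss over time follows
   `Y = (Y0 − Plateau)·e^(−K·t) + Plateau`; half-life is `ln 2 / K`.
5. **Dose-response.**  Cellular readouts (IL-8 pg/mL, %eGFP⁺, CD69 MFI)
   against ligands/cell are fitted with the log-logistic model
   `Y = Bottom + (Top − Bottom)/(1 + 10^((log10 EC50 − log10 X)·h))`,
   with background subtraction, below-detection → 0 imputation,
   normalisation to the per-dataset maximum, and EC50 aggregation.
6. **Bead counting.**  Quantitation-bead standard curves convert MFI to
   molecules per cell, with degree-of-labelling correction and flagged
   extrapolation — an independent counting route.

A `simulate` module generates every input from the same generative
models with known ground truth, so the full chain is testable without
instrument data.

## Worked example

Fit a simulated cell-suspension quench titration and count ligands:

```python
import ligandquant as lq
from ligandquant.simulate import GroundTruth, gen_quench_titration

truth = GroundTruth(scenario="demo", seed=7, x0=1.494e-7, noise_cv=0.02)
series = gen_quench_titration(truth, n_points=14)
fit = lq.SegmentalRegression.from_series(series).fit()
print(fit.summary())
count = lq.ligands_per_cell(fit.x0, volume_l=1e-4, cells=1e6, sites_per_ligand=3)
print(f"ligands per cell: {count.ligands_per_cell:,.0f}")
print(f"density: {count.density_per_um2:,.0f} per um^2")
```

```
Segmental linear regression (n=14, converged=True)
  intercept1 = 50.2079  (se 7.2)
  slope1     = 1.91263e+08  (se 8.52e+07)
  slope2     = 3.9658e+09  (se 3.48e+07)
  x0         = 1.47991e-07  (se 2.7e-09)
  sse        = 862.852
ligands per cell: 2,970,748
density: 4,244 per um^2
```

The fitted inflection (148 nM dye, true value 149.4 nM) says the 10⁶
cells in 100 µL bound that much biotin-4-fluorescein before free dye
appeared; at three sites per trivalent ligand this is ~3.0 million
ligands per cell, ~4,200/µm² — the saturating ligand load.  A shared-K_D
global fit of eleven simulated SPR repeats:

```python
from ligandquant.simulate import gen_equilibrium_series
series = gen_equilibrium_series(
    GroundTruth(kd=6.8e-6, bmax=100.0, hill_h=0.46, seed=1), n_series=11)
print(lq.SharedAffinityModel(series).fit().summary())
```

```
Global equilibrium affinity fit (11 series, n=396, converged=True)
  shared KD = 6.94754e-06 M  (se 3e-07)
  mean Hill slope = 0.457  (SEM 0.014)
```

recovers the generating K_D of 6.8 µM within its standard error.

There is also a CLI (`ligandquant quench-fit | binding-calibrate |
spr-fit | decay-fit | dose-response | beads-calibrate | simulate | run`)
operating on long-form CSVs; `ligandquant run` executes the whole
quench → counting → calibration → dose-response chain from one set of
inputs and writes an auditable JSON summary.

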