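# Methods

This note documents the models implemented in `ligandquant`, the
assumptions behind them, the defaults the underlying assays leave open,
and what the synthetic-data generators do and do not emulate.

## Segmental regression and the saturation inflection

A quench titration is modelled as a continuous two-segment line:
`Y = intercept1 + slope1·X` below the breakpoint `x0` and
`Y(x0) + slope2·(X − x0)` above it.  Given `x0` the model is linear in
the remaining three parameters, so `SegmentalRegression.fit()` profiles
`x0` over every midpoint between adjacent distinct concentrations,
solves each conditional problem by ordinary least squares in closed
form, and polishes the best candidate with a bounded scalar minimiser.
Profiling is globally reliable where a generic 4-parameter optimiser can
stall in local minima; the polish step recovers breakpoints that fall
between grid candidates (noiseless data are recovered to ≤1e-6 relative
error).  Constraints and conventions:

* the breakpoint is restricted strictly between the 2nd and (n−1)th
  distinct concentration, so each segment always has ≥2 points;
* ties in sse resolve to the smallest `x0` (the conservative saturation
  estimate);
* continuity at `x0` holds by construction of the design matrix;
* standard errors come from the Jacobian of the full four-parameter
  model at the optimum (the `x0` column is `slope1 − slope2` on the
  right segment, 0 on the left).

Negative background-corrected fluorescence is retained, never clipped,
to keep the least-squares estimates unbiased.

## Counting conversions

Counting assumes complete binding of biotin-4-fluorescein to the
coupling protein; the assumption is recorded in every `LigandCount`.
`L = x0·V·N_A/(C·B)` with the 2019 SI exact Avogadro constant
(configurable only for testing).  The uncertainty of `x0` is reported
but not propagated into `L` (`x0_se_propagated = False` flags this).
Densities use a 700 µm² cell surface — a 15 µm sphere (706.9 µm²)
rounded to the nearest hundred, matching the convention the counts are
compared against.

## Saturation binding and absolute calibration

Cell-binding titrations use the one-site isotherm
`Y = Bmax·X/(KD_app + X)`, where `KD_app` is an operational,
avidity-laden half-saturation concentration, not a solution dissociation
constant.  Starting values are data-driven (`Bmax ← max(y)`, `KD_app ←`
first concentration whose signal exceeds half the maximum).  The
population statistic behind `y` (median vs geometric mean) is carried as
metadata because both are legitimate summaries of a skewed per-cell
distribution.

Absolute calibration replaces the *fitted relative* `Bmax` with the
quench-derived count at saturating coupling concentration, keeping
`KD_app` — so relative and absolute curves share their half-saturation
point exactly.  "Saturating" is taken as the highest tested
concentration on the fitted plateau (within 5% of `Bmax`); the pipeline
records which concentration was used.  Interpolation at any requested
concentration is permitted; requests outside the fitted range are
answered but flagged as extrapolation.

## Shared-K_D equilibrium affinity

Equilibrium SPR series follow the Hill isotherm
`Y = Bmax·X^h/(KD^h + X^h)`.  Repeats differ in immobilisation level
(hence `Bmax`) and, empirically, slightly in `h`, but share one
underlying `K_D`; the global fit therefore shares `K_D` across series,
leaves `Bmax` and `h` per-series, and reports the mean Hill slope with
its across-series SEM.  A `share_h` switch exists for sensitivity
analysis.  All parameters are optimised as natural logarithms
(positivity, conditioning) and reported on the natural scale with
delta-method standard errors from the Gauss–Newton covariance.
Degenerate series (<4 points, non-positive concentrations) are excluded
with a warning and recorded in the result.

### Weighting

The wide-dynamic-range nonlinear fits — Hill equilibrium (single and
global), one-site saturation, and log-logistic dose-response — default
to **relative (proportional) least squares**: residuals are divided by
the model mean (floored near zero).  Fluorescence, RU and cytokine
readouts have noise that scales with the signal, and under constant-CV
noise relative least squares is the maximum-likelihood objective; with a
shallow Hill slope (h ≈ 0.46) it roughly halves the sampling error of
the shared `K_D` compared with unweighted fitting.  `weighting="none"`
restores plain least squares (the default of common curve-fitting GUIs)
everywhere; the purely linear fits (control lines, segmental regression,
bead standards) are always unweighted.  Reported `sse` is always the raw
(unweighted) residual sum of squares so fits are comparable across
weighting choices.

## Surface decay

`Y = (Y0 − Plateau)·e^(−K·t) + Plateau` with `t` in minutes and `y`
normalised to the value at `t = 0`; half-life is `ln 2 / K`.  Fitting
starts at `t = 0` by default; `from_peak=True` drops points before the
maximum for time courses showing a transient initial rise after ligand
reconstitution.  Non-decaying inputs (K ≈ 0 or `Y0 ≤ Plateau`) are
flagged, not silently returned.

## Dose-response

The four-parameter log-logistic model on a log10 dose axis:
`Y = Bottom + (Top − Bottom)/(1 + 10^((log10 EC50 − log10 X)·HillSlope))`,
with a fixed-slope (HillSlope = 1) variant for CD69/CAR analyses.  The
free parameter is `log10(EC50)`, loosely bounded around the dose range
so degenerate data cannot push it to infinity; an EC50 outside 10× the
dose range is flagged.  Zero-dose wells cannot sit on the log axis; they
enter the objective as direct observations of `Bottom` (the model's
X → 0 limit).  Conventions:

* below-detection readouts are set to 0 *before* background
  subtraction; negative corrected responses are retained unclipped and
  flagged;
* %positive gating thresholds at a control quantile (default 0.99,
  1.0 = control maximum), subtracts the control's own %positive and
  floors at zero — the quantile is configurable because gate placement
  on negative controls has no universal numeric rule;
* normalisation divides by the dataset's own maximum (maximum becomes
  exactly 1) and leaves EC50 invariant;
* EC50s aggregate as arithmetic mean ± sample SD across experiments;
  fold changes are reported both exact and rounded to the nearest
  integer, since comparisons are usually quoted as integer folds.

## Bead quantification

Bead standard curves regress capacity on MFI, linear scale by default
(the manufacturer convention for the emulated kits) with log-log
available.  Sample MFIs are background-subtracted before inversion;
non-positive corrected MFIs yield a count of 0 with a flag.  Counts
divide by the degree of labelling (fluorophores per molecule).
Extrapolation above the top bead is allowed and flagged, but estimates
beyond 10× the top bead capacity raise an error rather than report a
number the standard cannot support.  Note that the quench-based and
bead-based routes are internally consistent but need not agree with each
other on real cells (epitope accessibility and antibody valency differ);
the package asserts round-trip consistency of each route, not
cross-route equality.

## Synthetic data

Generators draw from exactly the models above plus multiplicative
Gaussian noise, with defaults chosen as typical instrument precision:
2% CV for plate-reader fluorescence, 5% CV for SPR response, 3% CV for
normalised decay MFI, 10% CV for cellular readouts.  Per-cell copy
numbers are lognormal (arithmetic CV 0.5) with the arithmetic mean
following the one-site isotherm, so the median is `mean/√(1+cv²)` —
consistent with median/geometric-mean population summaries.  Equilibrium
repeats use 12 concentrations × triplicate injections spanning
1e-3–50 × K_D (the upper bound reflecting what a soluble analyte stock
physically permits for a micromolar K_D), with lognormal per-series
`Bmax` jitter and normal `h` jitter.  Dose-response experiments add a
background offset, generate negative controls from background alone, and
censor readings at or below a configurable detection limit to zero.

Identical seed + parameters give bit-identical output.  The generators
reproduce curve shapes and noise magnitudes, not instrument artefacts
(plate edge effects, carry-over, spectral spillover, cytometer
compensation); recovery tests therefore bound statistical error under
the assumed noise model, not systematic error on real data.

Closed-loop tolerances are asserted as medians over seeded replicate
studies (e.g. inflection within 5% at 2% noise over 100 seeds, shared
K_D within 5% over replicate 11-series studies, EC50 median error ≤10%
over 200 experiments), because single-realisation errors at these noise
levels legitimately exceed the median bounds.

## Input/output conventions

Concentrations normalise to molar on read (M/mM/µM/nM/pM), time to
minutes, AU/RU pass through; the long-form CSV dialect is
`series_id, role, x_value, x_unit, y_value, y_unit, replicate` with
row-level validation errors reported by line number.  Results serialise
to schema-versioned JSON carrying parameters, standard errors, sse, n,
convergence flags, seed and software version.  The pipeline logs every
default it applies (statistic, gate quantile, weighting, saturating
concentration) so a run is auditable; reruns on identical inputs and
seed produce identical JSON.

## Problem sizes

The test suite and acceptance script use simulation sizes that keep each
property suite to seconds on one core (e.g. 14-point titrations, 5,000–
100,000-cell populations, 15–200 replicate studies per recovery bound);
these sizes were chosen so that Monte-Carlo error on each asserted
median is small relative to its tolerance.

## Known limitations

* `x0` uncertainty is not propagated into ligand counts (flagged in
  output) — a delta-method propagation would be straightforward but the
  counting chain's dominant errors are the complete-binding and
  surface-area assumptions, which no error bar captures.
* Kinetic (time-resolved) SPR, two-site/cooperative cell binding,
  internalisation mechanisms and mechanistic receptor-triggering models
  are out of scope.
* The Hill slope below 1 is treated purely descriptively; the package
  does not adjudicate between site heterogeneity and negative
  cooperativity.
* Bead MESF/ABC unit chemistry and spectral compensation are upstream of
  this package: bead capacities are taken as given.
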