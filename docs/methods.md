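# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and the limitations of `stoichscape`.

## Elemental landscape layers

Forage quantity is carbon areal density on the natural-log scale
(log g C/m²) and forage quality is nitrogen composition (% N), each a
single-band 30 m raster with a nodata mask over unpredicted habitat
(water, wetlands, non-forest). The carbon layer is never exponentiated for
modeling; all statistics and coefficients are on the log scale, because
the back-transform convention of published raw-scale summaries is
ambiguous while the log-scale summaries are internally consistent. Cell
`(r, c)` covers a half-open square with row 0 at the south edge; a point on
a shared cell edge belongs to the cell to the right/above, so extraction is
deterministic everywhere.

### StDM emulation

The stoichiometric distribution model (StDM) is represented as a Gaussian
identity-link linear model of an elemental measure on six landscape
predictors (normalized aspect, slope, elevation continuous; landcover with
2 levels, stand height with 4, dominant species with 3, dummy-coded with
the first declared level as reference). This is the simplest functional
form consistent with how such models are summarized by an R² and used as
prediction surfaces. `fit_stdm` is ordinary least squares with the
residual SD taken from the residual variance on `n − p` degrees of
freedom; rank-deficient designs raise an error naming the collinear
columns (identified by QR column pivoting). `predict_stdm` optionally adds
per-cell `N(0, residual_sd²)` noise under an explicit seed so prediction
scatter can be emulated; with noise disabled, fit → predict reproduces the
fitted values exactly.

### Correlated random-field simulator

`simulate_elemental_pair` builds two Gaussian random fields by smoothing
white noise with a Gaussian filter whose length scale is the
`spatial_range` in meters (default 90 m = 3 pixels; 0 gives white noise),
then mixes them with weights `(ρ, √(1−ρ²))`. The second field is first
*empirically* orthogonalized against the first and each field is affinely
rescaled, so the sample mean, SD, and cell-wise Pearson correlation equal
the targets exactly rather than only in expectation. Default targets are
the pooled two-study-area summary (C: mean −1.65, SD 0.89 log g/m²;
N: mean 2.78, SD 0.28 %; r = −0.01). A zero target SD yields a constant
layer, and a nonzero correlation combined with a zero SD is rejected as
impossible. Smoothing uses wrap-around boundaries so edge cells are not
variance-deflated.

## Scales of foraging

Study areas and home ranges are minimum convex polygons: the fraction
`level` (default 0.95) of points closest to the arithmetic centroid
(computed once, not iteratively) is retained — `ceil(level·n)` points —
and hulled. Area is reported in km²; all coordinates are planar meters and
no geographic-CRS math exists anywhere in the package.

Availability designs:

* random points at 22/km² inside the study-area MCP, rejection-sampled
  over the bounding box and restricted to non-nodata cells so the nominal
  count `round(area·density)` (ties to even) lands entirely in valid
  habitat;
* uniform grid points at 70/km² inside home ranges, with lattice spacing
  `1000/√density` m. Lattice nodes sit at cell centers of a lattice
  anchored at the polygon envelope's lower-left corner (first node half a
  spacing in, no jitter). Center anchoring was chosen over corner
  anchoring because corner-anchored inclusive nodes systematically
  overshoot the nominal density through the envelope boundary (81 vs 70
  nodes on a 1 km² square); node filtering keeps only nodes inside the
  polygon and on predicted habitat.

Cell membership for within-polygon statistics uses the cell-center
point-in-polygon test with boundary points counting as inside (shapely
`covers`), and both `polygon_stats` and the within-polygon C–N Pearson
correlation match exhaustive per-cell enumeration exactly.

## Track simulation

The simulator is the generative mirror of the patch-scale estimator. At
each 2-h step, `n_candidates` (default 50 — deliberately more than the
analysis's 10 available steps, to better approximate the continuous
kernel) endpoints are drawn from a gamma step-length × von Mises
turn-angle kernel relative to the previous realized heading; candidates on
nodata or outside the raster are redrawn (an agent with no valid candidate
after 100 rounds raises a trapped-agent error); one endpoint is chosen
with probability ∝ `exp(β_C·C + β_N·N + β_CxN·C·N)`. The first heading is
uniform on (−π, π] since a turn angle is undefined without a prior step.
Fix dropout removes fixes (never the first) with the configured
probability, producing genuine timestamp gaps so the gap-elimination rule
downstream is exercised; no interpolation is ever performed. Every
stochastic operation takes an explicit seed or Generator.

The default movement kernel for synthetic data is gamma(shape 2,
scale 150 m) — mean 300 m per 2-h step, a realistic early-summer moose
travel rate — with von Mises(μ = 0, κ = 0.5) turn angles (mild forward
persistence). The fixture dataset (`make_fixture_dataset`) builds two
study areas on one shared grid separated by a nodata strip, with
area-specific elemental targets (C mean −1.92/SD 0.89 and N 2.82/0.27,
r 0.11; C −1.41/0.82 and N 2.74/0.28, r −0.04), 3% nodata speckle, four
animals per area cycling through known coefficient triples, tracks
starting May 25 so the June 1 – July 16 seasonal window actually trims
fixes, and 5% dropout.

## Selection models

**Cleaning.** Fixes are subset to the early-growing-season window
(June 1 – July 16, closed, applied within every year) and to predicted
habitat; counts removed are logged.

**RSF (landscape, home range).** Logistic regression of used (1) vs
available (0) on C, N, and C×N, by Newton/IRLS implemented in the package
(statsmodels is used only as an independent oracle in the tests):
iterations capped at 100, convergence at gradient norm < 1e-8, step
halving on likelihood decrease. A converged gradient with numerically
saturated probabilities (|η| > 18) is treated as complete separation: the
fit is returned with `converged=False` and a warning, never silently
dropped. Standard errors come from the observed information; the null
log-likelihood is the closed-form intercept-only value. Duplicating every
available point k times shifts the intercept by −ln k and leaves slopes
unchanged *in the rare-use limit*; at moderate used:available ratios the
slope invariance is approximate (verified to ~1e-3 at a 1:100 ratio).

**iSSA (patch).** Consecutive fixes whose time difference matches the fix
interval within a tolerance (default 1 min) become steps; larger gaps
split bursts and the spanning step is dropped. Turn angles are
counterclockwise-positive, wrapped to (−π, π]; the first step of a burst,
and any step following a zero-length step (undefined heading), carries no
turn angle and forms no stratum. The movement kernel is fit by maximum
likelihood: `scipy.stats.gamma` with location fixed at 0 for step lengths
(zero lengths excluded — the gamma support is positive), and a von Mises
fit via the mean resultant length with κ obtained by inverting
`I₁(κ)/I₀(κ)`, capped at 1e3 with a warning for fully concentrated
angles. Ten available steps per stratum share the observed start point
with lengths and turns drawn from the fitted kernel; candidates landing
outside predicted habitat are dropped (not redrawn), mirroring the data
cleaning, and strata with fewer than 3 surviving candidates — or whose
used endpoint is unpredicted — are discarded and logged. Strata whose
available candidates have constant C and N (collapsed kernel) are flagged
as uninformative.

The conditional logistic regression maximizes the stratified partial
likelihood (no intercept) by Newton's method with the same convergence and
step-halving rules; per-stratum softmax terms are max-shifted for
stability and the implementation is verified against brute-force
enumeration to 1e-10. Covariates are C, N, C×N, step length (untransformed;
the log-step-length coding is available as a column for alternative
formulas), cos(turn angle), and the movement × elemental interactions
(step length × C, step length × N, cos(turn) × C, cos(turn) × N). Terms
with zero within-stratum information are flagged. The null log-likelihood
is evaluated at β = 0 (`Σ −log nₛ`).

**Pseudo-R².** McFadden's `1 − ll/ll₀`, clamped to [0, 1]; the flavor is
recorded in the output metadata. Patch-scale values are not directly
comparable to RSF values because the null models differ.

**Pooling.** Pooled models naively concatenate rows across units (no
random effects). At the landscape scale, per-area available samples are
unioned; a pooled landscape row is emitted only when there is more than
one study area (with a single area it would duplicate the area row).

## Trade-off synthesis

A unit's tactic is the sign of β_CxN with a neutrality band of one
standard error by default (the band is configurable; no published
threshold exists). The interaction-vs-correlation test is weighted least
squares of β_CxN on the unit's within-polygon C–N Pearson r with weights
1/SE² (standard WLS; 1/SE is offered since "weighted by standard error"
admits both readings), returning slope, t, and two-sided p. The
collar-year effect test is a plain one-way ANOVA (textbook between/within
mean-square ratio; identical groups return F = 0, p = 1 by convention).
Scale comparison reports, per unit, the interaction coefficients and
tactic labels at the home-range and patch scales, whether the tactic
switched (both scales non-neutral with opposite signs), and the magnitude
change.

## Problem sizes and determinism

Simulation-based checks use sizes chosen to balance statistical resolution
against desk-scale runtimes: recovery experiments run 50 replicates of
2,000-step tracks (iSSA) or 5,000-row tables (RSF); calibration uses a
300×300 grid; pipeline-level tests use two-area fixtures of a few hundred
fixes per animal. All randomness flows from explicit seeds through
`numpy.random.SeedSequence` stream splitting, so fixed-seed runs are
byte-identical.

## Limitations

* The synthetic landscapes are stationary Gaussian fields with a single
  smoothing scale; real StDM surfaces inherit structure from categorical
  covariates (sharp stand boundaries) and are non-Gaussian. Passing
  calibration and recovery tests therefore demonstrates estimator
  correctness under the stated generative model, not the fidelity of any
  particular field system.
* The track simulator has no home-range attraction, memory, or
  habitat-dependent movement kernel, so simulated home ranges are
  random-walk artifacts; landscape-scale selection in synthetic data is
  neutral by construction.
* Pooled fits ignore individual heterogeneity (no mixed effects), exactly
  as in the naive-pooling design they reproduce.
* C and C×N are strongly collinear when N has a small coefficient of
  variation (as % N does); individual coefficients then carry large
  standard errors even though the fit is valid, and Wald CIs remain
  well-calibrated. Interpret single coefficients jointly with the
  interaction.
* Phosphorus layers, biomass allometry, leaf chemistry, and secondary
  metabolites are out of scope.
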