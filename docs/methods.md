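# Methods

This note records the models, estimators, numerical choices and known
limitations behind each module, in the order data flows through the
pipeline.

## Competitive-binding rate law (`binding`)

The germination rate of a spore exposed to L-alanine (agonist) and
D-alanine (competitive inhibitor) is

    rate(L, D) = α · L / (k_l + L + g·D),   g = k_l/k_d,

the equilibrium active-receptor fraction scaled by a maximal rate α.  The
equilibrium assumption (binding fast relative to downstream signalling)
makes the surface depend only on the two dissociation constants and α.

Parameters and units:

- `alpha` (h⁻¹): maximal germination rate; the same unit as the CDF-slope
  estimator in `traces`, so fitted surfaces and measured rates are
  directly comparable.  Default 1.
- `k_l`, `k_d` (mM): dissociation constants.  The package's reference
  values are 0.026 and 0.0052 mM.  The ratios L/k_l, D/k_d in the model
  require concentration units for both constants.
- Concentrations of zero are legal everywhere; log spacing is purely a
  grid-construction concern (`log_grid`).

`bound_fraction` implements the algebraically equivalent
(L/k_l)/(1 + L/k_l + D/k_d) as a separate code path; the test-suite
cross-checks the two to machine precision.

The germinate/dormant phase diagram (`germination_region`,
`classify_concentration`) needs a rate cutoff.  The default is 0.1·α,
configurable: the choice sets where the boundary sits but not its shape —
in the high-D regime the boundary approaches the constant-ratio line
L/D = g·t/(1−t) (t = threshold/α), a unit-slope line in log-log space,
which is the ratiometric signature.

## Least-squares fitting (`fitting`)

`CompetitiveBindingModel.fit()` minimises Σ(rate_obs − rate_model)² over
(α, k_l, k_d), parameterised in log10 space with box bounds 10⁻⁶–10³ in
natural units.  Choices:

- **Loss on untransformed rates** (default): the measured quantity is a
  CDF slope with roughly additive error.  A `loss="log"` variant
  (log1p-rates) is available for maps whose noise scales strongly with
  the mean.
- **Multi-start**: a deterministic 3×3×3 grid — α seeded at {0.5, 1, 2}×
  the map's maximum rate, k_l and k_d at three log-spaced points spanning
  the positive concentration range of the grid.  Best residual wins; ties
  go to the first-found.  `scipy.optimize.least_squares` (TRF) with
  xtol = ftol = gtol = 10⁻¹⁰: the problem is cheap, and tight tolerances
  make noiseless recovery a crisp oracle (observed ≲10⁻¹⁵ relative error).
- **Identifiability guards**: at least 3 cells with L > 0; non-constant
  rates; at least one cell with both L > 0 and D > 0 (otherwise k_d never
  enters the residual).  Violations raise `NonIdentifiableError` rather
  than returning a silently unconstrained fit.
- Cells are equally weighted.

`parameter_recovery_study` is the validation harness: per replicate it
generates a noisy map (`gen_rate_map`), refits, and summarises per-
parameter relative errors (median, IQR).  At the study conditions used
throughout (8×8 log grid over 10⁻³–10 mM, 5% multiplicative noise, 50
replicates) the median relative error of each dissociation constant is
~5%, comfortably inside the 10% validation band; replicate fit failures
are recorded, not raised.

## Diffusion of opposing gradients (`diffusion`)

Forward-time centred-space (FTCS) integration of ∂c/∂t = D ∂²c/∂x² for
each enantiomer independently, with:

- diffusion coefficient 1×10⁻⁵ cm²/s for both species;
- 2 cm pad discretised at dx = 0.005 cm, dt = 1 s → stability factor
  D·dt/dx² = 0.4 ≤ 1/2 (checked at configuration time, before stepping);
- source strips modelled as *depleting initial conditions* appended to the
  pad ("additional pad length"), default width 0.2 cm — thin relative to
  the pad;
- zero-flux outer boundaries (a sealed dish; mass cannot leave).  The
  update conserves the discrete total mass identically; the solver
  verifies ≥ 6 h runs at ~10⁻¹⁵ relative drift.  The Laplacian is
  computed as (left + right) − 2·centre so mirrored configurations give
  bitwise-mirrored profiles;
- positions reported from the pad's left edge, excluding the source
  extensions, matching how distances are calibrated in the imaging
  experiment.

Validation oracle: the semi-infinite step solution
C(x,t) = (C0/2)·erfc(x/(2√(Dt))), valid while the boundaries are out of
diffusive reach; at t = 600 s the solver matches it to <0.01% of C0.
Halving dx (and quartering dt) moves the 6 h profile by <10⁻³% of the
source concentration.

`predict_spatial_germination` links concentration histories to an
observable: per position the cumulative hazard H(x) = ∫₀ᵀ rate(L(x,t),
D(x,t)) dt (trapezoid over recorded times, endpoint interpolated), and
p_germ = 1 − exp(−H).  The exponential-hazard link is a modelling choice —
the constant-hazard counterpart of the trace module's generator — and is
pluggable (`hazard_to_prob`).  Under the two-source preset (0.1 mM L
left, 0.2 mM D right) the predicted germination front is ~30% steeper
(max |dp/dx|) than with the L source alone: the inhibitor gradient
sharpens the spatial response.

## Trace analysis (`traces`)

- Plateaus: mean of the first/last 3 frames (configurable).  A spore
  counts as germinated only if its post plateau fell below 50% of the pre
  plateau *and* the trace crosses the midpoint (pre+post)/2.
- Germination time: the earliest frame whose intensity is *strictly*
  below the midpoint — frame-resolution calling, no interpolation.
- The CDF keeps never-germinators in the denominator, so its plateau is
  the germinated fraction, and padding a cohort with dormant spores
  rescales the maximum rate exactly by the dilution factor.
- Maximum germination rate: the largest least-squares slope over all
  windows of 3 consecutive CDF points (equal to (y₃−y₁)/(t₃−t₁) for
  equispaced frames), earliest window on ties, converted to h⁻¹.

At the validation conditions (1,000 spores, hazard 1 h⁻¹, 5-min frames,
6 h movie, 5% trace noise) ≥99% of calls land within one frame of truth
and the rate estimate sits within 15% of the hazard.  The estimator has a
known ~8% downward bias at this cadence — the 3-point secant under-reads
the initial slope of 1−e^(−rt) — partially offset by the max-over-windows
selection; both effects shrink with finer frames.

## Image quantification (`imaging`)

Segmentation: normalise → Gaussian denoise (σ = 1 px) → unsharp mask
(radius 2 px, amount 1.0) → Otsu threshold → connected components →
area ∈ [min, max] px and optional mean-intensity floor.  The denoise step
matters: Otsu's criterion fails on a sparse-foreground histogram whose
background mode is widened by high-pass-amplified pixel noise.  Area
defaults (20–500 px) are sized for ~1 µm spores at 103.6 nm pixels;
synthetic fields use bounds matched to their optics.  On synthetic fields
at SNR 5 and ~5% coverage: 100% detection, 0% false positives, centroid
error < 1 px.

Classification: germinated iff the background-subtracted mean intensity
at the endpoint frame fell strictly below (1 − 0.5)× its initial value
(background = median outside all footprints).  Frames are assumed
co-registered — registration/stitching of raw strips is out of scope.

Strip maps: per-state masks dilated by a disk (default radius 20 px);
pixels claimed by both states are assigned i.i.d. uniformly from a seed.
Fraction vs distance: centroids binned by horizontal distance (1 mm
default) from the origin at the pad edge nearest the L source; empty bins
carry n = 0 and an undefined fraction; an optional per-bin subsample flag
mimics region sampling.

## Competition statistics (`competition`)

Viable counts: plates inside the countable window (30–300 colonies,
standard plate-count practice, configurable) are pooled as
Σ colonies / Σ (dilution · volume) — the Poisson MLE, equivalent to
weighting each plate's rate by its plated dilution-volume.  No countable
plate → nearest-to-window fallback, flagged; all-zero series → 0, flagged
(a legitimate kill result).

Yield ratio: ratio of arm means N_nat/N_germ (the paper-style single
ratio per species), SEM by the first-order delta method from per-arm
SEMs, verdict `dormancy_advantage` / `germination_advantage` /
`indeterminate` (±SEM interval spanning 1).  A zero forced-arm mean
reports an infinite ratio with a flag rather than raising.  Calibration,
measured over 1,000 seeded synthetic experiments per true ratio
{0.2, 1, 5} at the default design (6 replicate wells per arm, 3-step
dilution ladder): the ±2·SEM interval covers the truth in 91.5–92.6% of
runs — above the 90% validation bound but below the 95.4% normal ideal,
as expected for an SEM estimated from few replicates.

## Synthetic data (`synthetic`)

What the generators emulate, and what they deliberately do not:

- `gen_rate_map`: rate-law mean × (1+ε), ε ~ N(0, cv) truncated so rates
  stay ≥ 0; default grid log-spaced 10⁻³–10 mM (4 orders of magnitude)
  plus a zero row/column.  No spatial correlation between cells.
- `gen_trace_cohort`: constant-hazard (exponential) germination times,
  censored at movie end; phase-darkening begins at the first frame
  at/after the event and completes within `transition_frames` frames
  (default 1); additive white Gaussian noise.  Real germination-time
  distributions need not be exponential — the hazard choice is the
  simplest one consistent with a rate-based model and is the module
  boundary to swap for e.g. a gamma law.  No photobleaching, drift, or
  focus loss.
- `gen_spore_image_pair`: Gaussian-PSF spots (σ 2 px), uniform placement
  with minimum separation, Gaussian read noise; default 400 spores per
  256×1024 frame (~5% coverage, a densely seeded strip).  Germinated
  spots drop to a residual amplitude.  No shot noise, uneven
  illumination, or debris.
- `gen_species_table`: log-uniform (L, D) pairs over 10⁻³–10 mM; the
  `just_outside` rule places D up to one decade above the region boundary
  at each L, emulating secretion ratios that narrowly avoid triggering
  germination.
- `gen_cfu_experiment`: Poisson colony counts per plate; no plating
  efficiency or counting error beyond Poisson.

All generators are bit-reproducible given (config, seed) and share the
single rate-law implementation in `binding`.  Passing tests therefore
demonstrate internal consistency of the pipeline under these idealised
noise models — not robustness to the artefacts (drift, stitching error,
non-exponential kinetics, clumped spores) that real movies and plates
contain.

## Problem sizes

The validation studies use: 8×8 concentration grids with 50 fit
replicates; 6 h diffusion runs at the default discretisation (21,600
steps, ~480 bins); 1,000-spore trace cohorts; 300-spore synthetic frames;
and 300 seeded competition experiments per true ratio.  These sizes give
Monte-Carlo estimates whose sampling error is small against every bound
asserted, while the whole suite runs in well under a minute.

## Known limitations

- Point estimates only from the fit; replicate spread is the only
  uncertainty quantification (no profile likelihood or bootstrap).
- 1D diffusion without uptake, degradation, or convection; source strips
  deplete rather than act as reservoirs.
- The hazard link between rate and by-time-T germination probability is
  an assumption, isolated behind a pluggable strategy.
- Frame-resolution germination calling floors the achievable time
  accuracy at one frame interval.
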