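# Methods

## Model

The track model separates the movement process from the observation
processes. The process operates at the irregular time scale of the surface
position fixes: between fixes the whale's displacement is taken from the
1-Hz dead-reckoning integral, and a velocity-correction term **v**^cor — a
slowly varying bias absorbing water-current drift, sensor error, speed
mis-calibration and body-orientation assumption violations — accumulates
linearly over each segment. **v**^cor follows a first-order Gaussian random
walk whose increment variance is σ² × Δ (Δ in seconds, σ in m s⁻¹ as a
per-√s rate), independently in easting and northing. Because the recursion
`x_{j+1} = x_j + d_j + v_j Δ_j` is deterministic given (**x**₁, **v**^cor),
the latent positions and the correction path are two coordinate systems for
the same state.

This is deliberately an approximation: dead-reckoning error is *not*
modelled at the 1-Hz step, so uncertainty between fixes is underestimated,
mildly so when fixes are frequent (tenths per minute) and increasingly with
fix gaps.

Observation-error parameters are calibrated separately and held fixed:
estimating them jointly with a single track is hopeless, and the dedicated
tests measure them directly. GPS errors are location-scale Student-t per
dimension, binned by satellite count — scale falls from ~25 m (x) / ~34 m
(y) at 4 satellites to ~8/9 m above 8, while the shape rises from ~1
(Cauchy-like) to ~8 (near-Gaussian). The y/x scale ratio is ~1.3 throughout,
so errors are reported per dimension. Visual fixes use a multiplicative
Normal range error (SD 30.2 % by eye, 10 % by laser range finder) and a
wrapped-Cauchy bearing error (ρ = 0.897); a bearing-and-range pair induces a
strongly anisotropic position error, which is why the likelihood works in
polar residuals rather than a circular position error.

One reported calibration quantity is not reproduced: the source analysis
quotes a circular SD of 11.6° alongside ρ = 0.897, but standard circular-SD
formulas give ~27° for that concentration, so only ρ is carried.

## Conventions

Local frame: x = easting (m), y = northing (m), origin at the first observed
position, via an ellipsoidal transverse-Mercator projection centred on the
origin (unit scale; distortion < 1 ppm over the < 50 km extent of a
deployment; round-trip accuracy < 1 mm within 100 km). A fixed UTM zone
would behave identically away from zone boundaries but the deployments sit
at 74–79° N where zone widths shrink. Bearings are degrees clockwise from
true north in (−180°, 180°]; headings are assumed already referenced to true
north (no declination correction). Written in component form the velocity
expression (cos h, sin h) versus (sin h, cos h) is a pure axis-labelling
choice; this package fixes x = east and uses v = s·cos p·(sin h, cos h),
which is the reading consistent with the bearing transform
φ = atan2(d_east, d_north).

The first observation anchors the frame and supplies the informative prior
on **x**₁ (its own error family, centred at the origin); it is therefore
excluded from the likelihood, avoiding double counting. Other observations
merged onto the same surfacing remain in the likelihood.

## Pre-processing

Raw 50-Hz streams are decimated to 1 Hz with a polyphase FIR resampler
(unity DC gain, linear phase, linear-extension edge padding): constants pass
exactly and out-of-band energy drops > 40 dB. Pitch/heading come from the
standard tilt-compensated accelerometer/magnetometer construction. Speed is
estimated from |depth rate|/|sin pitch| during steep (|p| > 50°) ascents and
descents (central-difference depth rate; non-positive estimates dropped),
regressed as log(s) ~ N(β₀ + β₁L, σ_L) on the 66–94 Hz flow-noise level,
with both pitch and L low-pass filtered at 0.15 Hz (zero-phase
forward-backward FIR) to remove fluke-stroke oscillation. Predicted speed
uses the median back-transform exp(β₀ + β₁L) — the point estimate the
dead-reckoner needs — not the mean back-transform. Speeds at depths < 5 m
are replaced by linear interpolation between the bracketing deep values
(surface noise contaminates flow noise); runs touching a record end hold the
nearest defined value. The regression is refit per deployment. Fixes within
5 s of one another are merged onto a shared timestamp (GPS pairs to the
earlier time; visual fixes to the GPS time), and fix times are snapped to
the 1-Hz grid for the half-open displacement sums — sub-second intervals are
not prorated.

## Sampler

Fitting uses Markov chain Monte Carlo with two chains from over-dispersed
starts (a fix-following track with σ = 0.01; the zero-correction
dead-reckoning track with σ = 0.05), the classic split R-hat as the
convergence gate (≤ 1.05), and a burn-in/thinning schedule given by
`McmcConfig` (desk default 2 × 30,000 iterations, 10,000 burn-in, thin 5;
the full-length 2 × 280,000 / 200,000 / 5 configuration is
`PAPER_MCMC_CONFIG`).

Per iteration the sampler combines:

* **Local Metropolis sweeps in x-space.** Sampling the latent positions
  (rather than v^cor directly) makes dependence strictly local — site j
  touches only sites j±1, j±2 through the random-walk increments — so sites
  are updated in three conditionally independent colour groups (j mod 3),
  each group vectorised, with per-site Robbins–Monro scale adaptation during
  burn-in. Single-site v^cor updates would instead shift the entire
  downstream track (O(J²) per sweep) and mix far worse; the two
  parameterisations are a linear bijection with constant Jacobian, so the
  posterior is unchanged.
* **Joint path proposals by FFBS.** Conditionally on auxiliary
  scale-mixture variables the model is linear-Gaussian: a scaled-t is a
  Normal with Gamma(ν/2, ν/2)-mixed precision, and each visual fix gets a
  Gaussian surrogate at the observed range/bearing whose radial and
  tangential scales carry Gamma(1/2, 1/2)-style mixed precisions (the
  tangential scale (1−ρ)/√ρ · R is the small-angle Cauchy limit of the
  wrapped Cauchy). Whole paths are then drawn exactly by forward filtering /
  backward sampling (state (x, y, vx, vy); the deterministic position
  transition is handled in the backward pass by sampling v_j from its
  conditional and back-substituting) and accepted with an
  auxiliary-variable Metropolis correction. The GPS terms cancel identically
  in that correction (their mixture is exact); what remains is the bounded
  mismatch between the true visual densities and their surrogates and
  between the uniform and Gaussian v₁ priors. Acceptance is ~1 for GPS-only
  data and ~0.5 with visual fixes. FFBS runs every 10th iteration
  (`ffbs_every`); it dominates mixing, the local sweeps refine the
  non-Gaussian visual geometry between draws.
* **σ moves.** A centred random-walk update on (log σ_x, log σ_y) given the
  correction path, plus a non-centred (ancillarity–sufficiency) move that
  rescales the innovation path together with σ — without it σ and the path
  amplitude are mutually pinned and mix pathologically slowly — plus a
  whole-track translation move for global placement.

Degenerate inputs: fewer than two distinct fix times, satellite bins outside
1..6, unknown range methods, and non-finite initial log-posteriors raise
immediately. Zero displacement to a boat position is guarded (range floored
at 1 nm-scale epsilon); bearing likelihoods are computed in radians with
wrapped differences.

Posterior track realisations expand a fraction (default 10 %) of the stored
draws per chain into 1-Hz tracks: the dead-reckoning integral plus the
draw's initial position and accumulated per-segment corrections. At fix
times each realisation reproduces that draw's latent positions exactly; the
full-length configuration yields the reference count of 3,200 realisations.
Before the first and after the last fix, the nearest segment's correction is
extended.

## Synthetic data

The generator emulates the statistical structure the model assumes, at
field-like magnitudes: dive cycles of ~2 min (30 s surface, 30/30/30 s
descent/bottom/ascent at ±60° pitch), heading as a wrapped Gaussian random
walk (4°/√s), speed driven log-linearly by a slowly varying flow-noise level
(β₀ = −3, β₁ = 0.05, σ_L = 0.1, giving ~0.7–2.5 m s⁻¹) with the scatter
correlated over ~10 s so depth-rate speeds are self-consistent; GPS fixes at
surfacings (≥ 30 s apart, 90 % detection) with satellite counts at the
stationary-test proportions (11/13/16/18/17/24 % for 4/5/6/7/8/>8) and
scaled-t errors at the calibrated parameters; visual fixes roughly every
2 min from a simulated pursuit boat at a few hundred metres standoff, with
centred Normal percent-range and wrapped-Cauchy bearing errors. Process SD
defaults (σ_x = 0.014, σ_y = 0.012 m s⁻¹) are the strongest drift level
observed in the calibration deployments. Fix rates land in the observed
0.1–1.9 per minute band.

One design choice deserves emphasis: the drift truth is piecewise-constant
within a dive cycle and jumps at surfacings with variance σ² × elapsed — a
Gaussian random walk observed at the surfacing scale, which is exactly the
process the segment-scale model describes. A continuous 1-Hz Brownian drift
would be equally physical but makes the model see *segment-averaged*
increments, whose variance is (2/3)σ²Δ with MA(1) correlation; a fitted σ
then converges to √(2/3) ≈ 0.82 of the generating value as a structural
(not implementation) bias. Parameter-recovery experiments therefore use the
model-consistent generator; real-data σ estimates should be read as the
drift variability *at the surfacing scale*, not as an instantaneous
diffusion rate.

What the generator does not emulate: ocean-current fields with spatial
structure, tag slide (time-varying orientation offsets), behaviour-dependent
speed regimes, observer-specific visual biases, and surfacing detection
failure correlated with behaviour. Passing recovery tests on this generator
show the estimator is correct under the model's own assumptions; they do not
certify robustness to these violations.

## Scale of the bundled experiments

The test suite and the acceptance script run everything at desk scale chosen
as the smallest sizes at which the checks are statistically meaningful:
calibration refits at the stationary-test bin sizes (3,864–8,641) or
n = 5,000 for the visual quantities; an 8-h deployment (~240 fixes) with
2 × 30,000 iterations for drift-SD recovery; 2-h deployments with 2 ×
4,000–6,000 iterations (FFBS-driven mixing makes short chains adequate, and
split R-hat is checked every time) for cross-validation and the
linear-Gaussian oracle comparison. Standard errors quoted for the
calibration tables were verified by simulation where possible; where a
printed standard error is inconsistent with the observed information at the
stated sample size (the shape parameters and the y-dimension scales),
recovery checks use observed-information standard errors instead.

## Cross-validation

Held-out Fastloc-GPS fixes (the most accurate and least autocorrelated fix
type) score five track types: the posterior-mean state-space track, linear
interpolation between GPS fixes, linear interpolation between visual fixes,
and forced-point dead-reckoning (per-segment constant velocity bias, exact
interpolation of the training fixes) with constant speed or flow-noise
speed. Two designs: every-10th-fix removal (each fix validated once across
10 folds) and alternating blocks of five (10 shifted iterations, 50 %
omitted, each fix validated five times). Visual fixes sharing a held-out
surfacing (single mode) or falling within the held-out block's interval ±5 s
(block mode) are excluded from training. Errors are Euclidean distances at
the nearest 1-Hz sample, pooled over folds, then averaged per satellite bin
(mean ± SEM). On synthetic data at field-like rates the ordering is
state-space ≤ forced-point ≤ visual interpolation, and errors fall with
satellite count because the validation fixes' own measurement error is part
of the score.

## Known limitations

* Between-fix uncertainty is underestimated by construction (no 1-Hz
  observation model); a conditioned Kalman pass between surfacings would be
  the natural extension.
* σ is identified from at most a few hundred segments per deployment;
  its posterior is sensitive to the surfacing rate.
* The forced-point "stretching" definition (constant per-segment velocity
  bias) is the standard reading but other stretches exist.
* KS goodness-of-fit with estimated parameters is anticonservative; the
  package reports the plain test for comparability and a parametric
  bootstrap variant for correctness.
* Boat GPS positions are treated as error-free (average error < 3 m,
  small against the visual errors).
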