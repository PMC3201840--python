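# Methods

This note records the model, the numerical and design choices behind
`cgmcal`, and what the synthetic-data generator does and does not emulate.

## Kinetics

The sensor compartment is a single first-order exchange,
`dNIG/dt = p1 (BG(t) − NIG)`, on the scale of *normalised* interstitial
glucose: the raw interstitial kinetics have two rate constants (uptake
from blood, first-order disposal), but only their combination is
identifiable from sensor data, so NIG is scaled to equal BG at steady
state and a single rate `p1` (1/min) remains.  `1/p1` is the
blood-to-sensor delay in minutes.  The forcing function `BG(t)` is the
piecewise-linear interpolant of the observed BG series; outside the
observed window it is clamped to the boundary values, which never matters
for the study design (the BG window envelopes the SG window) but keeps
simulation robust.  Times are minutes from study start (17:00).

Because the forcing is linear in time between breakpoints, the ODE is
solved exactly: evaluation times and forcing knots are merged into one
ascending grid, and the closed form of a first-order linear ODE with
linear input is applied per segment.  The recursion is written with
`expm1` so that small `p1·dt` does not lose precision to cancellation.
A classical fixed-step RK4 integrator (stage values of the forcing via the
same interpolant) is retained purely as an independent numerical
cross-check; the two agree below 1e−6 mmol/L at step 0.1 min on random
piecewise-linear forcings.  Inner loops are `numba`-compiled with a pure
Python fallback.

## Observation model

Calibration periods are half-open and left-closed at each calibration
instant: a reading taken exactly at a calibration time uses the *new*
calibration, since calibration resets the sensor from that moment.  This
convention is isolated in `assign_periods`.

Within period `k`, `CIG = F_k·NIG + B_k`; `F_k` and `B_k` absorb the
unidentifiable sensor constants (current sensitivity, baseline current,
calibration gain and offset).  Residual variants:

* **basic** — `SG_j ~ N(NIG_j, σ_i²)`, one SD per individual;
* **calibrated** — `SG_j ~ N(CIG_j, σ_{ik}²)`, one SD per individual and
  period;
* **calibrated + AR** — AR(1) residuals with one-step conditional mean
  `φ_j = CIG_j + (F_{P[j]}/F_{P[j−1]})·ρ·(SG_{j−1} − CIG_{j−1})` and
  period-specific innovation SDs.  The F-ratio keeps the latent *current*
  error process continuous across a recalibration.  The first reading
  contributes no likelihood term: it defines the ODE initial state through
  the initial residual η₁, which removes the need for an explicit NIG₀
  parameter and, through an informative prior on η₁, discourages fits in
  which the whole CIG series sits a constant distance from the data.  The
  innovation SD across a calibration boundary is that of the *new* period;
  no additional rescaling of σ is applied at the boundary.

The forward simulator mirrors the likelihood exactly (same recursion, same
F-ratio), records the realised residual series, and never emits NaN;
non-positive simulated readings are possible in principle but the noise
SDs are tiny relative to glucose levels, and a warning is logged if it
happens.

## Hierarchy and priors

Transformed individual-level parameters get normal population
distributions: `log p1` and `log σ` with unknown means and unknown
log-SDs; calibration vectors `C_k = (B_k, log F_k)` bivariate normal with
mean `µ` and covariance `Σ` (three-level model), optionally with
individual-specific means `ω_i` and intra-individual covariance `Ω`
(four-level); `η₁ ~ N(0, sd_η₁²)` with `sd_η₁ ~ Unif(0, 0.5)` — the upper
bound makes initial residuals above 1 mmol/L unlikely.  Hyperpriors are
vague but proper: normal with SD 100 on every location and log-SD
parameter, inverse-Wishart with degrees of freedom equal to the dimension
(2) on `Σ` and `Ω`.  Prior centres default to a ~16-min delay
(`log p1` centre −2.8), a neutral calibration (`C` centre (0, 0)) and
`log σ` centre −1; the Wishart scale defaults to the identity.  All are
config-overridable; they are this package's defaults, chosen as weakly
informative round numbers on the relevant scales.

`population_summaries` reports natural-scale medians (`exp` of the
log-scale mean), log-normal CVs (`sqrt(exp(s²)−1)`) and plug-in 95%
ranges; `delay_prediction_interval` gives the posterior-predictive
interval for a new individual's delay, which is wider because it
propagates hyperparameter uncertainty.

`REFERENCE_FITS` stores the posterior-median population parameters
reported for the Guardian RT sensor under each model variant; the
calibrated + AR entry is the default generator population.

## The autocorrelation ρ and cut feedback

The AR process and the regression function are confounded: an
unconstrained fit drifts to ρ ≈ 1 with implausible CIG series, because
large-but-similar consecutive residuals are cheap.  Four treatments are
implemented:

* `free_bounded` — shared ρ with `logit(ρ/ρ_max)` given a vague normal
  prior; ρ_max defaults to 0.8.  On data whose residuals are more
  autocorrelated than the bound allows, the posterior piles up at ρ_max.
  An individual-ρ option (`rho_shared=False`) adds a normal population
  for `logit(ρ_i/ρ_max)`.
* `fixed` — ρ held constant.
* `distributional_constant` — ρ resampled every iteration from
  Unif(0.75, 0.85) while the likelihood is prevented from updating it (a
  cut: information flows prior → likelihood only).  Its marginal is its
  prior by construction; other parameters match a fixed-ρ = 0.8 fit up to
  Monte Carlo error while predictions carry honest ρ uncertainty.
* duplicated-data cut (`fit_duplicated`) — the SG data are used twice: a
  homoscedastic calibrated likelihood drives `B`, `F`, `p1`, the period
  SDs and all hyperparameters, and an AR(1) likelihood on the implied
  residuals drives an *unconstrained* ρ and its own innovation SDs.  A
  valve blocks information flow from the AR module back to the calibrated
  parameters, so the calibrated trajectory is bit-identical to a
  calibrated-only fit at the same seed (this is tested exactly, by RNG
  stream separation).  `cut=False` removes the valve as a negative
  control.

A caution from our simulations: under the duplicated cut the fitted ρ is
*attenuated* relative to the residual process that generated the data
(e.g. posterior median ≈ 0.8 on data generated with ρ = 0.9), because the
per-period calibration shifts absorb low-frequency residual drift and
short or glycaemically flat periods leave `(B_k, F_k)` diffuse.  The cut
guarantees plausible CIG series; it does not undo this absorption.

The choice of ρ_max itself is a user decision guided by CIG plausibility;
the mean |SG − CIG| per individual is reported as a diagnostic rather
than automated into a selector.

## Sampler

Adaptive random-walk Metropolis-within-Gibbs on transformed scales.
Conjugate Gibbs is used for `µ` (MVN), `Σ`/`Ω` (inverse-Wishart), `ω_i`
(MVN) and the scalar population means (normal); everything else is
Metropolis.  Step sizes adapt by Robbins-Monro toward 0.44 acceptance for
scalar updates and 0.23 for 2-blocks, during burn-in only.  The
calibration 2-blocks additionally adapt their proposal *shape* to the
running empirical covariance of the block (Haario-style): the `(B, log F)`
posterior is a strong ridge, and isotropic proposals stall on it.  Missing
SG readings are latent variables: Gibbs draws where the full conditional
is Gaussian (always in the iid variants; interior readings in the AR
variant) and a Metropolis step for a missing first reading, which enters
the initial condition.  Deviance (−2 log likelihood over data terms) is
recorded per kept draw.

Initialisation: individual parameters at the prior centres plus
seed-controlled jitter (SD 0.1), η₁ at 0, missing readings at linear
interpolants of the observed series.  A non-finite initial posterior
raises an error naming the offending individual.  Runs are deterministic
given the seed; chains use per-chain substreams, and the duplicated-cut
fit gives its AR module an independent substream so the valve property
holds exactly.

Default run length is 20 000 iterations with 10 000 burn-in and thinning
by 5 — a scaled-down default that recovers the reference population's
means on full-size simulated studies in about two minutes per fit on one
CPU; longer runs are a single config change.  Adaptation freezes at the
end of burn-in, so the post-burn-in chain is a valid fixed-kernel sampler.

DIC uses `pD = D̄ − D(θ̄)` with `θ̄` the posterior means of the
likelihood-level parameters *on their sampled (transformed) scales* and
missing readings at their posterior-mean imputations.  On weakly
identified, strongly curved posteriors (flat-BG periods) `D(θ̄)` can
exceed `D̄`, the familiar negative-pD pathology of DIC; the Dbar column
is the robust quantity for the three- vs four-level comparison.

## Synthetic data

The generator reproduces the reference study's *design*: a 19-h window
(17:00 → 12:00), BG every 15 min (m = 77, grid starting at 0), SG every
5 min (n = 228, grid starting at minute 5 — the only convention matching
both counts), calibrations shortly after the start and every 6 h
(ψ = 20, 380, 740, 1100 min; 5 periods), meals at 18:00 and 08:00 with
carbohydrate draws of mean 87 g, SD 23 g, and a small fraction of SG
readings missing completely at random (default 1%, the mechanism being
unspecified in the source study).

The BG curve is statistical, not physiological: a normal baseline
(mean 8, SD 1.5 mmol/L), gamma-shaped meal excursions whose peak height is
0.05 mmol/L per gram of carbohydrate (an invented but scale-plausible
conversion, configurable) reached ~40 min after the meal, plus a
discretised Ornstein-Uhlenbeck noise process (stationary SD 0.5 mmol/L,
correlation time 45 min), clamped to 2.5-20 mmol/L.  It produces forcing
inputs with realistic magnitude, smoothness and meal structure; it does
*not* model insulin action, meal absorption kinetics, exercise or
hypoglycaemic episodes, so passing tests say nothing about those regimes.
In particular hypoglycaemic readings are rare under the defaults, and
glycaemic-range residual summaries on synthetic data have few
hypoglycaemic members — as, with 15 residuals, they did in the reference
study.  Overnight the simulated BG is flat apart from the OU noise, which
leaves `F` in the overnight calibration period only weakly identified;
this mirrors a real limitation of calibration-period models rather than a
generator artefact.

Individuals are drawn from `REFERENCE_FITS["calibrated_ar"]` by default.
Each individual's latent NIG starts at the forcing value at the first SG
time, making the generator self-consistent with the η₁-based initial
condition used by the likelihood.  Generating truths are returned (and
written by the CLI) separately from the dataset so fits can be blinded.

## Numerical details

* Period assignment: `searchsorted(ψ, t, side="right") + 1`; ties go to
  the new period.
* Quantiles everywhere use numpy's default linear interpolation of order
  statistics (type 7), for bit-reproducible fixtures.
* The exact-solver recursion saturates rather than overflows for extreme
  `p1` proposals; prior-only runs can push log-SD hyperparameters to
  magnitudes where `exp` saturates to `inf`, which the conjugate updates
  treat as an infinitely diffuse population (reducing to the prior).
* Proposals implying a non-positive initial NIG are rejected outright
  (physically implausible state).
* Glycaemic ranges: hypo ≤ 3.9 < eu ≤ 10 < hyper, in mmol/L, boundaries
  inclusive on the left group.

## Known limitations

* The BG forcing is treated as error-free; a measurement-error sub-model
  for BG is out of scope.
* Residuals are Gaussian; heavier-tailed (t, Johnson) innovations are not
  implemented.
* DIC's pD is unreliable under the curved ridges of weakly identified
  calibration periods (see above).
* The sampler is random-walk based; it is adequate at the reference study
  size but would benefit from gradient-based methods on much larger
  designs.
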