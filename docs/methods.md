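# Methods

This note documents the models implemented in `divevis`, the synthetic
data the tests run on, and the numerical choices made where the design
was genuinely open.  Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The scientific setting

A pursuit-diving seabird hunts by sight.  How much light reaches its prey
depends on solar elevation above the horizon, cloud cover, and the
transparency of the water column, summarized by Secchi-disc depth (Zsd,
metres; the depth at which a standard white disc disappears — larger
means clearer).  The package's question is whether these visibility
covariates shape (i) the bird's broad-scale movement decisions, and
(ii) its fine-scale diving: how often and how deep it dives.

## Track and dive processing

**Regularization.** Raw GPS fixes are linearly interpolated — in
longitude and latitude independently — onto an exact grid (default 300 s)
anchored at each segment's first fix.  Interpolation never crosses a raw
gap longer than 1 h; the track splits there.  Linear (rather than
great-circle) interpolation is negligible at 5-min seabird scales.

**Trips.** A foraging trip is a maximal period spent more than 5 km from
the colony lasting at least 6 h, with points inside a 1 km colony radius
discarded.  A brief dip back inside 5 km ends the trip; no bridging rule
is applied, because any such rule would be an invention — the attrition
is logged instead.

**Steps and turns.** Step length is the haversine distance (R = 6371 km)
between consecutive fixes; turning angle is the signed change of
great-circle bearing at interior points, positive counter-clockwise.
The von Mises emission used downstream is symmetric about its mean, so
inference does not depend on the sign convention.  Coincident fixes give
a zero step and an undefined turn (treated as missing).

**Dives and bouts.** Depth series are decimated to 0.5 Hz (integer
ratios only; no resampling interpolation).  A dive is a maximal run of
samples strictly deeper than 1 m; its maximum depth and duration are the
run maximum and length.  Inter-dive surface intervals mix a fast
(within-bout) and a slow (between-bout) Poisson process; the two-process
frequency model

    f(t) = Nf·λf·exp(−λf t) + Ns·λs·exp(−λs t)

is fitted to binned intervals (default 5 s bins) by nonlinear least
squares **on the square-root scale**, a variance-stabilizing choice that
keeps sparse tail bins — including empty ones — informative.  Fitting
log-frequency of nonzero bins only, the textbook presentation, biases
the slow rate upward; switching to the √count scale brought the
recovered bout-ending criterion (BEC) within a few percent of the
analytic intersection

    bec = log(Nf λf / (Ns λs)) / (λf − λs)

across seeded replicates.  Fits are flagged unusable when the optimizer
fails, the rates are within a factor 1.5 of each other, or the slow
process carries fewer than 5 intervals.  Dives attach to the nearest
fix in time (dive start as the reference; exact ties go to the earlier
fix; dives farther than half a fix interval from any fix stay
unassigned and are counted).

## The movement HMM

Three states — rest, area-restricted search (ARS), transit — emit step
lengths (gamma, parameterized by mean and s.d., with an optional
zero-inflation mass for coincident fixes) and turning angles (von
Mises).  Transitions follow a multinomial logit with diagonal reference:

    Γ_ij(z) ∝ exp(β0_ij + βz_ij z),  i ≠ j;   Γ_ii ∝ 1.

The likelihood is the scaled forward recursion with a per-step Γ(z_t),
computed in a numba kernel (log-space shifts per step; no underflow at
T = 10⁴⁺).  Fitting maximizes this directly over unconstrained working
parameters (log for means/s.d./concentration, logit for masses and the
initial distribution, identity for the periodic turn means) with
L-BFGS-B and jittered multi-starts; Zsd is standardized internally and
coefficients are reported per metre.  Fitted models are canonicalized by
ascending step mean, so state indices are stable under label switching.
Starting values are data-driven (step-length terciles); the nested
intercept-only fit makes a good warm start for the covariate model.

Decoding is Viterbi (ties to the lowest state index); posterior state
probabilities come from the scaled forward–backward recursion.
Transition and stationary curves over a Zsd grid carry delta-method
confidence intervals from a numerical Hessian of the working-scale
likelihood, with a parametric-bootstrap alternative.  Model comparison
reports ΔAIC, decoded-state agreement, and — reading "decoded ARS" as a
dive predictor — hit rate P(ARS | dive), miss rate, and precision
P(dive | ARS).

## The penalized-spline models

All smooths are low-rank penalized regression splines built on cubic
B-splines with second-order difference penalties (P-splines):

* 1-d shrinkage smooths: the penalty's null-space eigenvalues (constant
  and linear directions) are replaced by 0.1× the smallest positive
  eigenvalue, so a single smoothing parameter can shrink the whole term
  — trend included — to zero.  This is the mechanism behind
  "selected against": a covariate with no support ends near 0 EDF.
* cyclic smooths (time of day, period 24 h): B-splines on wrapped knots
  with a circulant difference penalty; f(0) = f(24) by construction.
* tensor products (solar angle × Zsd): row-wise Kronecker of marginal
  bases with one shrinkage penalty per margin — appropriate because the
  two covariates live on unrelated scales (degrees vs metres).
* random intercepts: indicator columns under a ridge penalty.
* the movement-state covariate of the depth model: unpenalized dummies
  with rest as the reference level.

Each smooth absorbs a sum-to-zero constraint by reparameterization, so
it is identifiable next to the intercept.

**Fitting.** Penalized IRLS for the two families: negative binomial with
log link (dive counts per 5-min fix; θ estimated by matching the Pearson
statistic to the residual degrees of freedom) and Gaussian with identity
link (bout maximum depth).  Smoothing parameters minimize a
restricted-likelihood (REML-type) score by performance iteration: IRLS
runs to convergence, the working response and weights are frozen, and
the score

    (n − p₀)·log(RSS_p) + γ·(log|XᵀWX + S_λ| − log|S_λ|₊)

is minimized over log λ by coordinate grid sweeps plus a Nelder–Mead
polish (each evaluation is one small penalized solve), after which the
cycle repeats.  Freezing the working model matters: re-converging IRLS
inside every λ evaluation lets each candidate reshape its own working
data and measurably over-fits null terms.  γ = 1.2 multiplies the
complexity (log-determinant) part of the score, stiffening both
smoothing and the select-against-zero behaviour.  The scale is profiled
out for both families, since a working model's dispersion is rarely
exactly 1 even for a count family.

**AR(1).** Serial correlation along trips enters as first-order
whitening of the working rows within trips at a plug-in ρ — the pooled
lag-1 autocorrelation of working residuals — in a single two-step pass.
The depth model uses no correlation structure.

**Reporting.** Per-term EDF is the trace of the influence matrix over
the term's columns.  Per-term tests are Wald statistics on the penalized
coefficients against the Bayesian posterior covariance with EDF-rounded
reference degrees of freedom — approximate by construction and labelled
as such.  A term counts as "selected against" when its EDF < 0.01 and
its largest fitted effect is below 10⁻³ response s.d.  Goodness of fit
is deviance explained; for the count model a presence AUC is added:
score = P(count > 0) = 1 − (θ/(θ+μ̂))^θ per fix, ranked against observed
presence (the Mann–Whitney identity, cross-checked against scikit-learn
in the tests).  The 1-d smooth path was also cross-checked against the
reference R implementation of penalized-spline REML fitting on a shared
dataset (test suite, `TestReferenceImplementation`).

A replication caveat: under a true null covariate, REML-type smoothing
estimates have the classic boundary-mixture behaviour — a minority of
replicates land at a finite λ with ~0.5–1 EDF instead of the boundary.
The test suite's shrinkage checks account for this by testing the
replicate fraction, not every replicate.

## The synthetic-data generator

The generator is the package's study stand-in, and its defaults are the
emulated study's conditions:

* **Environment.** Daily Zsd fields are lognormal surfaces (exp of a
  smoothed Gaussian field) with arithmetic mean 7.5 m and s.d. 2.6 m on
  a ~4 km grid; hourly cloud maps a smoothed space-time Gaussian field
  through the normal CDF onto [0, 100]%; bathymetry is a deterministic
  ramp (water depth positive down, deepening away from the colony).
  Cloud is independent of Zsd by default; a config flag can couple them
  for confounding experiments.
* **Movement.** The same 3-state HMM the analysis fits, at 5-min
  resolution: step means (0.08, 0.7, 3.0) km per 5 min — transit is
  ~36 km/h flight — concentrations (0.8, 0.4, 8.0), a 5% zero-step mass
  at rest, and clarity effects on the natural scale: transit→ARS slope
  +0.5 per m, ARS-leaving slopes −0.2 per m (clearer water promotes and
  sustains searching).  Positions advance on a local tangent plane
  (adequate at few-km steps) and reflect off the grid margin so
  covariates stay defined.  Birds rest a day at the colony between
  trips.
* **Dives.** Counts per 5-min fix are negative binomial (θ = 2.5) with
  log-link predictor: a Gaussian bump in solar angle × Zsd (peak at 18°
  elevation and 8 m Zsd — the dawn/dusk, moderately-clear-water peak), a
  24 h cosine in time of day peaking at 17:00 UTC, and N(0, 0.25²) bird
  intercepts, hard-gated to zero below −6° solar elevation (civil
  twilight).  The base rate was set so simulated birds log ~55–70 dives
  per bird-day and the fitted rate model explains ~20–25% of deviance
  with presence AUC ~0.73, matching the magnitudes the emulated field
  study reported.  Maximum depths follow an identity-link predictor
  (light × clarity surface, weak negative cloud slope, transit dives
  3 m shallower) with N(0, 4²) noise truncated to (1.05, 42] m.
* **Bout structure.** Within a fix window, inter-dive gaps draw from the
  fast/slow mixture (λf = 1/20 s⁻¹, λs = 1/600 s⁻¹, 70% fast), rounded
  to the 2 s sample grid with a 3-sample minimum, so a known BEC exists.
  Each dive renders as a symmetric triangle on the 0.5 Hz grid whose
  peak sample equals the true maximum depth and whose every sample
  exceeds 1 m — detection therefore recovers the truth exactly, which
  the round-trip tests assert.
* **Seeding.** All randomness flows from one root seed through named
  substreams (`env`, `track`, `dive`); identical configs give identical
  outputs byte for byte.

Two lean samplers (`simulate_fix_table`, `simulate_bout_table`) draw the
model covariates with independent margins for the smooth-recovery
experiments.  This is deliberate: on a physical track, solar angle and
time of day are nearly deterministic functions of each other within a
single colony and season, and that concurvity is a property of the
sampling design, not of the estimator under test.

**What the generator does not emulate:** central-place trip geometry
(outbound/return commuting), wind and energetics, surface prey capture,
tag failure and fix loss, and real spatial structure in prey. Passing
recovery tests therefore demonstrate that the estimators recover the
processes they model, at realistic sizes and noise levels — not that
those processes are the whole story in real tracking data.

## Problem sizes and tolerances

The verification suite runs at deliberately chosen scales: exact-oracle
checks (forward/Viterbi vs enumeration over all 3^T paths) at T ≤ 7 with
100 parameter draws at 10⁻⁸; HMM recovery at 20 replicates of 50 tracks
× 500 steps (emission parameters within 15% relative, the clarity slope
within ±0.15, AIC preferring the covariate model, in ≥18/20); BEC
recovery within 20% of the analytic criterion in ≥18/20 at n = 2000
intervals; smooth recovery at n = 5000 fixes (surface correlation ≥0.9,
null-term EDF < 0.5 in ≥80% of 20 replicates) and n = 1500 bouts
(transit contrast within ±1 m of −3 m); solar elevation within 0.5° of
an independently-formulated ephemeris (the package uses the Meeus-series
equations, the oracle an Astronomical Almanac formulation; neither
applies refraction).  End-to-end runs use a 3–4 bird colony over 1–2 day
trips, which exercises every stage in a few minutes; all stages scale
linearly in fixes and samples.

## Known limitations

* The HMM assumes the covariate is known at every fix; measurement error
  in gridded Zsd is not propagated.
* Per-smooth p-values are approximate (penalized Wald); treat them as
  descriptive, as the reported EDFs carry the selection story.
* The NB θ moment estimator absorbs any extra-negative-binomial
  dispersion (e.g. latent rate autocorrelation) rather than flagging it.
* AR(1) whitening uses a single plug-in ρ; iterating ρ to convergence is
  not implemented (a second pass changed estimates negligibly on
  synthetic data).
* The depth model treats bout maxima as independent given covariates;
  no explicit within-trip correlation (none was needed on synthetic
  residuals).
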