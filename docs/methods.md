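# Methods

This note records the models, their assumptions, the defaults that matter,
and the choices made where the design was genuinely open.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Snowmelt dates

A grid cell's snowmelt date is "the day after the continuous snow-cover
period", estimated from a weekly boolean cover series.  Weekly granularity
forces two conventions, both configurable:

* **Run selection.**  The continuous cover period is the maximal run of
  consecutive covered weeks containing a winter anchor day (default
  day-of-year 60, i.e. 1 March).  If the anchor week is bare, the first
  covered run after the anchor is used; if cover disappeared before the
  anchor, the last run before it.  Anchoring prevents an isolated autumn
  or summer snow shower from redefining the melt date.
* **Week-to-day.**  Melt = the day after the last calendar day of the
  run's final week.  If the run reaches the end of the series the melt was
  not observed; the same day is returned with a right-censoring warning.

Site dates are unweighted means over a caller-chosen cell set (e.g. the
two cells nearest a field site).  Validation regressions of remote-sensed
against field-observed dates are ordinary OLS via `phenology.fit_trend`;
no bespoke operation exists for them.

## Trend regressions and the path analysis

`fit_trend`/`fit_covariate` are OLS with the slope tested by the 1-df
model-comparison F (model with the term vs. intercept-only), which equals
t².  Missing values are dropped pairwise; a constant predictor raises.

The path model is recursive and fully observed: with all variables centred
(dates and year),

    arrival_staging = b1.1 t + e1
    snowmelt        = b2.1 t + e2
    arrival_arctic  = b3.1 t + b3.2 snowmelt + b3.3 arrival_staging + e3
    cranefly        = b4.1 t + b4.2 snowmelt + e4
    clutch          = b5.1 t + b5.2 snowmelt + b5.3 arrival_arctic
                      + b5.4 cranefly + e5

with independent Gaussian errors per equation.  Because the system is
triangular and errors independent, the joint posterior factorises; each
equation is sampled separately on its complete cases (equation-wise
deletion — series lengths differ in real data).  Priors: Normal(0, 100²)
on coefficients, half-Cauchy(5) on residual sds — weakly informative at
the day scale of the data; recovery tests guard against prior sensitivity.
Evidence per path is P(|b| > 0) = max(P(b > 0), P(b < 0)) over the
posterior.  Point dates are used as given (no measurement-error submodel).

*Identifiability caveat for recovery experiments:* shrinking every
residual sd makes each variable an almost-deterministic function of time,
so multi-predictor equations become collinear and their coefficients
cannot be recovered at any sample size.  Recovery tests therefore shrink
only the terminal (clutch) equation's noise; the upstream noise is what
identifies the downstream designs.

## Staging arrival dates from count sessions

Arriving birds in year k are spread over days as Gaussian(T0_k,
sigmaT0_k²).  The expected count of session (site i, day j, year k) is

    log N = a0 + total_k + site_i + log(hours)
            − (day − T0_k)² / (2 sigmaT0_k²) − ½ log 2π − log sigmaT0_k

so that the daily intensity integrates to exp(a0 + total_k + site_i +
offset) — the kernel carries its full normaliser (verified numerically to
1e−6).  Counts are negative binomial with size r and p = r/(r + N), hence
mean N: flocking makes counts overdispersed relative to Poisson.

Filters mirror the data-collection protocol: sessions between day-of-year
100 and 145 (10 April – 25 May) inclusive, and only sites with more than
100 sessions recording at least one bird ("records" read as sessions;
configurable).  Year and site effects are sum-to-zero centred for
identifiability with a0.  Priors: T0_k ~ Normal(window midpoint, 15²) d,
sigmaT0_k ~ half-Normal(10), r ~ Exponential(0.1), effects ~ Normal(0, σ)
with half-Cauchy(5) hyper-sds.  Years with no positive count are flagged
unidentifiable.  Model fit is checked by a posterior-predictive p-value
with the Freeman–Tukey discrepancy Σ(√y − √E[y])² (the discrepancy is a
free choice; Freeman–Tukey is variance-stabilising for counts).

## Arrival mass, refuelling rates, compensation

Arrival-type captures give cell means W0_ks by year × sex and a pooled
within-cell residual sd per sex (fixed cell means rather than a
mixed-model fit; cells here are well filled).  For refuelling-type
captures the model is

    W_i = W0_i + alpha_ks (T_i − T0_i),
    W0_i ~ Norm(W0_ks, sigmaW0_s²),  T0_i ~ Norm(T0_k, sigmaT0_k²)

Both latents are Gaussian and enter linearly given alpha, so they are
integrated out exactly: W_i | alpha_ks ~ Norm(W0_ks + alpha_ks (T_i −
T0_k), sigmaW0_s² + alpha_ks² sigmaT0_k²).  This keeps the sampling space
to the annual rates plus hyperparameters.  Rates are exchangeable around a
sex-specific linear function of annual lugworm density; years without a
density measurement draw from a sex-level exchangeable mean instead
(an open choice — the alternative of dropping those years discards mass
data needlessly).  Rates are not truncated at zero.  Priors: intercepts
Normal(0, 10²) g d⁻¹, slopes Normal(0, 5²) g d⁻¹ per worm m⁻²,
sds half-Normal(10).

Refuelling time is RT_k = (Arctic arrival − lag) − T0_k with a fixed
migration lag (default 5.5 d, a tracking-derived duration for the
staging-to-breeding leg).  The compensation arithmetic holds the survival
linear predictor beta_RT log RT + beta_alpha log alpha constant:
alpha_new = alpha_old (RT_old / RT_new)^(beta_RT / beta_alpha).

## Survival

The CJS likelihood conditions on first capture and uses the chi recursion
for the never-seen-again tail; it matches an exhaustive latent-fate
enumeration to 1e−10 on short histories (an acceptance check).  Survival
is modelled on the logit scale with a small formula grammar over
{tsm, sex, time, log_rt, log_alpha} and pairwise interactions; covariates
enter as unstandardised natural logs (rate × time is multiplicative, so
logs make it additive).  Sex enters survival only; resighting is
year-specific (or constant).  Fitting is L-BFGS-B from multiple seeded
starts (default 5); standard errors come from the inverse observed
information (finite-difference Hessian).

QAICc = −2 logL/ĉ + 2K + 2K(K+1)/(n_eff − K − 1).  ĉ is an input
(default 1.118, a typical median-ĉ value for colour-ring resighting data;
its estimation procedure is out of scope).  n_eff is the number of
releases, counted as detections before the final occasion — the MARK
convention is ambiguous across platforms, so the choice is explicit and
logged here.  Pairwise contrasts are reported as QAICc(simpler) −
QAICc(complex), positive favouring the complex model.  Apparent survival
equals true survival only absent permanent emigration; for a population
with a single staging site the two coincide, but the code documents rather
than asserts this.

## Population trend

Latent abundances follow deterministic exponential growth with one shared
λ (no process noise — a process-noise variant is deliberately out of
scope); observations are negative binomial with site-specific sizes r_i,
independent priors across sites (Exponential(0.01)).  Priors: log λ ~
Normal(0, 0.5²); log N_i1 ~ Normal(log first observed count, 1²).
Missing site-years contribute nothing.  The headline quantity is
P(λ < 1), the fraction of posterior draws below 1.

## Tracks

Great-circle distances use the haversine formula (R = 6371 km).  A
stopover is a maximal run of fixes all within 25 km of the window's first
fix spanning ≥ 24 h; anchoring on the first fix (rather than a centroid)
is deterministic and order-stable, and the scan resumes after each
accepted window so stopovers never overlap.  Leg duration runs from the
last fix inside the origin region to the first later fix inside the
destination; regions are lon/lat boxes or point-radius circles.  Fixes are
assumed pre-filtered; an opt-in 120 km h⁻¹ speed sanity filter is
provided.  Durations are resolved only to the fix interval.

## Synthetic data: what it does and does not emulate

The generator simulates each stream from the exact generative model the
corresponding fit assumes, tied together by one simulated annual truth
(staging arrival from the path model, Arctic arrival, refuelling time,
lugworm density, realised rates).  Defaults are study-scale: 25 years,
7 count sites with ~13 sessions each per season and log-uniform 1–8 h
effort, ~55 arrival and ~125 refuelling captures per year and sex, 3995
marked birds over 15 occasions, 6 winter roosts over 15 years, λ = 0.96,
snowmelt advancing 0.73 d yr⁻¹, rates ~5–7 g d⁻¹ responding to density at
~0.2 g d⁻¹ per worm m⁻², survival logit slopes 1.43/2.86 (male/female) on
log RT and 0.98 on log rate.  Track geometry is waypoint-driven (winter →
staging → breeding with 3.8 d and 5.5 d legs); the nominal 55 km h⁻¹
ground speed only labels the default, as detector tests depend on relative
geometry alone.

Deliberately not emulated: missing phenology years (real series lengths
vary, handled by equation-wise deletion but generated complete), spatial
habitat structure, location-error classes, within-individual mass
trajectories, double counting, and emigration.  Passing recovery tests
therefore show the estimators are correct under their own assumptions —
not that real data meet those assumptions.

## Numerical choices

* Ensemble MCMC (emcee) with walkers ≥ 2 × dimension, burn-in equal to the
  kept draws, initialised from a crude moment/OLS start; positive
  parameters are sampled on the log scale with the Jacobian in the prior.
  Convergence: split-walker R-hat ≤ 1.05 on every parameter; fits carry a
  `converged` flag and are never silently accepted.
* Log-intensities are clipped at ±30 (log scale) before exponentiation to
  keep early walker excursions finite; the clip is far outside the
  posterior's support in all fitted problems.
* CJS optimisation uses ftol 1e−12 / gtol 1e−8; ties between restarts are
  resolved toward the first best value found.
* All dates are integer day-of-year in generated observation tables;
  model-scale dates (T0_k and friends) are real-valued.
* Degenerate inputs raise or warn explicitly: no snow season, no
  qualifying count sites, zero-positive-count years, single-day capture
  years, all-zero winter counts, non-positive refuelling times.

## Problem sizes in the routine checks

Test and acceptance runs use reduced but study-shaped problems — e.g.
1–8 simulated years for the arrival and refuelling fits, 400–5000 marked
birds for CJS, 50 replicate fits for the null calibrations — chosen so the
whole suite completes in minutes while keeping every estimator in the
regime the study operates in (posterior sds comparable to the published
standard errors).  The acceptance script prints its sizes alongside each
quantity.

## Known limitations

* The ensemble sampler is adequate for these unimodal, low-dimensional
  posteriors but would need replacing (e.g. HMC) for strongly correlated
  high-dimensional extensions.
* The refuelling model treats T0_k and sigmaT0_k as known inputs from the
  arrival fit; their posterior uncertainty is not propagated (matching the
  two-stage design of the analysis it implements).
* P(|b| > 0) is a posterior tail probability, approximately uniform under
  a null effect — it is evidence of direction, not a calibrated test.
* The QAICc effective-sample-size and ĉ conventions follow explicit,
  logged choices; comparisons against software using other conventions
  will differ in the third decimal of QAICc, not in rankings at the
  reported effect sizes.
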