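# godwitflyway

Statistical models for a flyway-scale question in migration ecology: when
Arctic spring advances, can a long-distance migratory shorebird keep up —
and at what survival cost?  The package implements, as one tested pipeline,
the chain of models needed to answer it for a population that winters in
West Africa, refuels once at a temperate staging site (the Wadden Sea) and
breeds on Arctic tundra:

1. **Snowmelt phenology** (`snowmelt`) — annual melt dates from weekly
   remote-sensed snow-cover series, per grid cell and site.
2. **Phenology trends and path analysis** (`phenology`) — OLS trend and
   covariate regressions with 1-df model-comparison F tests, and a
   recursive Gaussian path model (structural equations) of how time and
   snowmelt drive crane-fly emergence, arrival and clutch initiation,
   fitted by MCMC with per-path evidence P(|b| > 0).
3. **Staging arrival dates** (`arrival`) — annual mean arrival date T0_k
   from effort-heterogeneous citizen-science count sessions: a Gaussian
   arrival pulse on the log scale with a log-hours offset and
   negative-binomial counts, `p = r / (r + N)`, plus the season-window and
   site-quality filters and a posterior-predictive (Freeman–Tukey) fit
   check.
4. **Arrival mass and refuelling rates** (`refuel`) — sex-specific annual
   arrival masses; refuelling rates `alpha_ks` from staging body masses
   via `W_i = W0_i + alpha_ks (T_i − T0_i)` with the Gaussian individual
   latents integrated out exactly; a linear lugworm-density effect on
   rates; refuelling time `RT_k`; and the compensation arithmetic
   `alpha_new = alpha_old (RT_old / RT_new)^(beta_RT / beta_alpha)`.
5. **Apparent survival** (`survival`) — Cormack–Jolly–Seber maximum
   likelihood with time-since-marking classes, sex, and year-level
   `log(alpha_ks)`, `log(RT_k)` covariates; QAICc model selection with an
   external overdispersion factor c-hat.
6. **Population trend** (`popgrowth`) — state-space winter roost counts:
   deterministic exponential growth `N_{i,k+1} = N_{i,k} λ` with
   site-specific negative-binomial observation error; reports P(λ < 1).
7. **Tracking** (`tracks`) — stopover detection (25-km radius, ≥ 24 h) and
   migration-leg durations from satellite fixes.
8. **Synthetic data** (`synthetic`) — forward-simulates every input stream
   from known ground truth under the models' own generative assumptions,
   so the whole chain is testable by parameter recovery without field data.

Bayesian fits use the affine-invariant ensemble sampler (emcee) with
split-walker R-hat diagnostics; CJS fits use numerical maximum likelihood
with observed-information standard errors.

## Worked example

```python
from godwitflyway import synthetic as syn, phenology as ph, popgrowth as pg

cfg = syn.SyntheticConfig(seed=1)          # 25-year study conditions
table = syn.gen_phenology(cfg)
print(ph.fit_trend(table["snowmelt_doy"], table["year"]))

counts = syn.gen_winter_counts(cfg)
print(pg.fit_popgrowth(counts, draws=2000, seed=2).summary())
```

prints

```
slope = -1.07 ± 0.13, N = 25, F = 63.16, P = 4.81e-08
{'lambda_mean': 0.9667, 'lambda_sd': 0.0090, 'lambda_q2.5': 0.9496,
 'lambda_q97.5': 0.9846, 'p_lambda_lt_1': 0.9997, 'converged': True}
```

The first line is the snowmelt advance in this simulated world (truth
−0.73 d yr⁻¹; one 25-year realisation of the configured residual noise
gave −1.07 ± 0.13).  The second is the winter-count trend: the posterior
for the growth multiplier λ (truth 0.96) and the posterior probability the
population is declining.

A command-line layer mirrors the library (`godwitflyway synth`,
`snowmelt`, `sem`, `arrival`, `refuel`, `cjs`, `popgrowth`, `tracks`); run
`godwitflyway --help`.

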