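# Methods

`lhprod` estimates how the prevalence of juvenile life-history pathways
(LHPs) in a stream-rearing salmonid responds to spawner density and stream
discharge, from rotary-screw-trap monitoring data.  The inference has three
stages, fit in sequence: a state-space model of daily emigrant abundance per
stream and age class, a mixture-based delineation of four emigration-timing
windows, and a penalized hierarchical generalized Beverton–Holt model of
annual LHP production.  A seeded synthetic-data generator stands in for
field data throughout the tests and the demonstration analysis.

## Stage 1 — daily emigrants past a screw trap

For each stream × age class (subyearling, yearling), the latent number of
emigrants passing the trap on season day *t* of brood year *y* is

    log m_{t,y} = mu_y + delta_t + eps_{t,y}

* `mu_y` — year level (fixed effect).  It is the level at the season's
  first day, because the seasonal profile is anchored there.
* `delta_t` — cross-year seasonal profile, a random walk with step SD
  `sigma_delta` and `delta_1 = 0`.  The random walk is deliberately
  non-stationary: seasonality is a trend, not noise around a mean.
* `eps_{t,y}` — year-specific deviations, a stationary AR(1) with
  innovation SD `sigma_eps`, autocorrelation `rho`, and stationary initial
  SD `sigma_eps / sqrt(1 - rho^2)` (the standard stationary convention, so
  the marginal variance of `eps` is constant over the season).

Trap capture probability is logit-linear in discharge:

    logit p_{t,y} = iota_y + kappa_y D_{t,y} + nu_{w(t)} + xi_{w(t),y}

with year intercepts `iota_y ~ N(beta0, sigma_iota)`, year discharge slopes
`kappa_y ~ N(beta1, sigma_kappa)` (note the nonzero means — the population
intercept and slope), and zero-mean week effects, where `w(t)` indexes
7-day blocks from the season start and `D` is discharge Z-scored per stream
× age class over operating days.  Mark–recapture trials inform `p` through
a binomial likelihood using discharge on the release day only (nearly all
recaptures occur on the release day, so this simplification costs little).
Fish below tagging size are assumed to share the tagged fish's capture
probability.

Catches are negative binomial with mean `m p` and variance
`mu + mu^2 * phi` — `phi` multiplies, so the Poisson limit is `phi -> 0`.
Outage days contribute no catch likelihood but remain in the process model,
so abundance across gaps is interpolated by the random-walk/AR(1) prior.

Estimation maximizes the marginal likelihood, integrating `delta`, `eps`,
`iota`, `kappa`, `nu`, `xi` out by Laplace approximation; fixed effects are
`mu_y`, `sigma_delta`, `sigma_eps`, `rho`, `phi`, `beta0`, `beta1` and the
four random-effect SDs (`sigma_iota`, `sigma_kappa`, `sigma_nu`,
`sigma_xi`), all estimated.

### Identifiability note

`mu_y` is the level at the anchor day.  When the true profile rises steeply
away from a sparsely informed season edge, the decomposition between
`mu_y`, `delta`, and `eps` near the anchor is weakly identified; the
marginal likelihood is nearly flat along that direction and the reported
standard errors of `mu_y` honestly reflect it.  Daily abundances `m_{t,y}`
and window totals — the quantities the pipeline consumes — are unaffected.

## Stage 2 — delineating the four LHPs

The cross-year mean of estimated daily abundance, pooled over streams and
years on a single brood-cycle day axis (day 1 = Jan 1 of the first calendar
year after spawning; yearling days exceed 365), is four-modal: spring,
summer and fall subyearling emigration plus spring yearling emigration.  A
four-component normal mixture is fit by EM to the day values weighted by
rounded abundance — equivalent to expanding each emigrant into one
observation of its day.  Pooling uses the cross-year *mean* rather than the
sum so high-abundance years do not dominate the timing signal (a `sum`
switch is provided).  scikit-learn's mixture EM takes no observation
weights, so the weighted 1-D EM is implemented here (sklearn serves as an
independent cross-check on expanded samples in the tests).

EM details: quantile-based initial means, common initial SD = span/8, equal
weights; 10 jittered restarts keeping the best likelihood; a component SD
collapsing below half a day triggers a restart, and exhausting restarts is
an error.  The log-likelihood is monotone non-decreasing per iteration and
recorded.

Cutoffs are the integer days minimizing the fitted mixture density between
successive component means (ties break to the smallest day, for
determinism); an argmin on the boundary of an inter-mean interval means the
modes merged and raises an error rather than fabricating a window.  The
four windows are common across streams and years, clipped to trap-season
coverage; no emigration is assumed in the winter gap between the
subyearling and yearling seasons, which undercounts total emigration
slightly but does not bias interannual comparisons.  Window totals
`M_{h,y,s}` are sums of daily abundance within windows.

### Parametric bootstrap of window totals

Uncertainty in `M_{h,y,s}` propagates to Stage 3 through a parametric
bootstrap: parameter sets are drawn from a multivariate normal defined by
the fixed-effect estimates and covariance; random effects are drawn from
their conditional Gaussian given each fixed-effect draw, using the
implicit-function linearization `du/dtheta = -H_uu^{-1} H_utheta` for the
mode shift plus conditional noise with covariance `H_uu^{-1}`.  Each draw
yields daily abundances and window totals; the log-mean `Mbar*` and log-SD
`sigma^Mbar*` across draws (default 10,000) summarize each (LHP, brood
year, stream) cell.

## Stage 3 — spawner-to-emigrant production by LHP

Expected emigrants per km of spawning habitat follow the Myers
generalization of the Beverton–Holt curve,

    J_{h,y,s} = alpha_{h,s} S^gamma_{h,s} / (1 + alpha_{h,s} S^gamma_{h,s}
                / Jmax_{h,s}) * exp(eps^J_{h,y,s})

with spawners `S` per km (redd counts index female spawners).  `gamma > 1`
gives accelerating (positive density-dependent) production, `gamma < 1`
with finite `Jmax` decelerating production; `gamma = 1, Jmax -> inf` is the
density-independent line.  The three shape parameters are lognormal across
streams within LHP.

Because three streams cannot estimate hyperdistribution SDs freely, all
hyper-SDs carry exponential regularizing penalties (common rate `lambda`),
and the log hypermeans of `gamma` and `Jmax` carry normal penalties
centered — on the natural scale, via `E e^X = e^{m + s^2/2}` — at 1 and at
`nu_Jmax = 15,000` per km respectively, with penalty SDs `tau` that are
themselves exponentially penalized.  The data must therefore earn any
density dependence; this replaces model selection across density-dependent
and independent forms.

Process errors decompose as

    eps^J_{h,y,s} = x'_{h,y,s} beta_h + omega_y l_{h,s} + eta_{h,y,s}

* covariates `x` (Z-scored within stream): log maximum daily discharge of
  the brood year's first winter (Nov 1–Feb 28/29) for every LHP; mean daily
  discharge of the first summer (Jun 1–Sep 30) for all but spring
  subyearlings, which emigrate before summer; log maximum discharge of the
  second winter for spring yearlings only;
* a shared annual latent factor `omega_y ~ N(0,1)` with loadings `l_{h,s}`
  inducing rank-1 correlation across LHPs and streams (one factor per year,
  shared across all series); the first loading is constrained positive (log
  parameterization) to fix the reflection symmetry;
* independent noise `eta_{h,y,s} ~ N(0, sigma_eta_{h,s})`, with
  exponentially penalized SDs.

Observations enter as penalties: `Mbar* ~ N(log J, sigma^Mbar*)` with the
bootstrap SD, and redd counts lognormal around latent spawners with SD 0.1
(≈10% CV).  Latent spawners, `omega`, `eta`, the `gamma`/`Jmax` hypermeans
and the stream shape parameters are random effects; hyper-SDs, `tau`s,
covariate coefficients, loadings, `sigma_eta` (and optionally the penalty
rates) are fixed effects.

### Penalty rates

The exponential penalty rates can formally be estimated as fixed effects
with their densities in the joint likelihood, and the package supports
this (`estimate_lambdas=True`).  The default fixes them at 1 per unit
scale: jointly maximizing an exponential rate and the scales it penalizes
is degenerate — the rate runs to its bound as the scales shrink, and we
observed exactly this collapse (all hyper-SDs and `tau`s pinned at zero,
every hypermean frozen at its penalty center).  A fixed, weakly informative
rate preserves the penalties' purpose without the feedback loop.

## Estimation machinery

All models share one mixed-model core: the joint NLL over (fixed, random)
is minimized over the random effects by Newton's method with analytic
gradients and sparse Hessians (assembled per-observation; factorized by
SuperLU in symmetric mode with diagonal pivoting, which certifies positive
definiteness and yields the log-determinant), giving the Laplace marginal
NLL.  The outer problem is L-BFGS-B over the transformed fixed effects
(variances on log scale, correlations on atanh scale) with
forward-difference gradients; perturbed evaluations warm-start from the
incumbent random-effect mode and take at most two Newton steps, which the
envelope property makes accurate to O(h^2).  No automatic-differentiation
package is available in the target environment, which motivated the
analytic-sparse-derivative design.

The idiosyncratic errors `eta` enter the Stage-3 likelihood linearly with a
Gaussian prior, so they are integrated in closed form (each observation SD
becomes `sqrt(sigma_Mbar*^2 + sigma_eta^2)`).  The Laplace approximation is
exact for linear-Gaussian effects, so this is the identical marginal
likelihood at roughly a third of the inner dimension; conditional `eta`
modes are recovered by Gaussian shrinkage of the residuals.

Numerical choices that matter:

* inner Newton: gradient tolerance 1e-8 with an Armijo line search and a
  ridge fallback; a Newton decrement below 1e-12·(1+|f|) counts as
  converged (the float-resolution floor of the objective);
* outer L-BFGS-B: gradient step 1e-4 on the transformed scale, `ftol`
  1e-9; Stage-3 log-scale parameters are floored at e^-3.5 ≈ 0.03 —
  statistically indistinguishable from zero for these penalties but far
  from the flat asymptote the optimizer would otherwise creep along;
* fixed-effect covariance: Stage 1 inverts a central finite-difference
  Hessian of the marginal NLL (step 1e-2); Stage 3, with ~56 fixed
  effects, uses the cheaper joint-precision Schur complement, which is
  accurate for location-like parameters and is also how standard errors of
  the penalized hypermeans (formally random effects) are propagated.
  Parameters pinned at a bound are profiled out of the covariance and
  reported with zero variance; remaining non-positive-definite directions
  are eigenvalue-clipped and flagged.

Wald intervals on `exp(mu_gamma)`/`exp(mu_Jmax)` come from the
joint-precision SEs; bootstrap intervals for fixed effects are available
through seeded multivariate-normal parameter draws.

## Synthetic data

The generator produces the full structure the pipeline assumes: seasonal
discharge (snowmelt freshet plus an autumn rain peak, lognormal daily
noise), lognormal spawner abundances observed as redd counts with 10%
lognormal error, recruitment per the Stage-3 model (default hypermean
`gamma` = 1.5/1.1/1.0/0.4 and `Jmax` = 12,000/9,000/1,480/2,500 per km
across the four LHPs, winter-discharge coefficients 0.37/0.10/−0.13/−0.22 —
the fitted pattern of the study system), four timing modes at brood-cycle
days 100/200/290/470, discharge-dependent capture around 8% with a negative
discharge effect, NB catches (`phi` = 0.05), outage gaps, and scheduled
mark–recapture trials.  Defaults are scaled to eight brood years and three
streams so the whole pipeline runs in minutes; the field program ran 13–22
years per stream.

Two generation modes, both seeded and bit-reproducible:

* **literal** — the daily layer follows the Stage-1 equations exactly
  (year means, random-walk profile, AR(1) deviations).  Recovery tests use
  this mode with a pure random-walk profile, because a deterministic
  multi-modal template conflicts with the random-walk prior at the anchor
  day and makes `mu_y` recovery meaningless as a calibration check;
* **coupled** — window totals come from the recruitment layer and the
  daily layer distributes them within windows (mode-shaped share times
  random-walk roughness and AR(1) deviations).  The Stage-1 model is then
  a flexible approximation rather than the literal generator — deliberate,
  mild misspecification of the kind field data carries.

What a green test does not establish: the generator does not simulate fish
size or growth (age classification is carried exactly, not inferred from
length), water temperature, hatchery dynamics, or inter-cohort density
effects; real trap data also violate the NB observation model in ways
(debris, partial-day operation) the outage mask only caricatures.

## Known limitations

* Emigration and survival are confounded: the production curves describe
  emergent LHP abundance, not mechanism.
* The `mu_y`/`delta` anchor-day flatness discussed above.
* The joint-precision covariance understates uncertainty in strongly
  curvature-coupled variance parameters relative to the exact marginal
  Hessian; Stage 1, where the recovery tests make quantitative SE claims,
  uses the exact (finite-difference) marginal Hessian instead.
* With three streams, hyperdistribution SDs are mostly penalty-driven;
  that is the design's intent, not an artifact.
* Very weak LHP modes (≲1–2% of emigrants) can defeat the four-component
  mixture — EM will split a dominant mode instead; the delineation raises
  an error rather than fabricating windows when interior minima are
  missing.
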