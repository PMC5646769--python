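# Methods

## Observation model

Trap catches are interval-aggregated: bottle *j* at site *s* in year *k*
accumulates biomass over the inclusive day range [τ₁, τ₂].  The model treats
the catch as normal about the sum of latent expected daily biomass,

  m_j ~ N(μ_j, σ²_j),  μ_j = Σ_t z_t,  σ²_j = Σ_t σ²_t,

with z_t = exp(y_t), y_t = c + log(λ)·k + x_t'β + u_s, and
σ²_t = e^{2y_t+v}(e^v − 1).  Two modelling commitments follow from the data:

* **Sum, then exponentiate — not the reverse.**  Because exposure intervals
  are unequal, log-transforming bottle totals would conflate interval length
  with abundance; the model sums daily expectations on the natural scale.
* **Variance on the log scale.**  σ²_t is the exact variance of a log-normal
  with log-mean y_t and log-variance v, so the residual spread v and the
  site variance σ²_site are directly comparable, both being variances of
  daily log-biomass.

The normal observation density admits negative masses with small
probability; at the default variance components the implied probability of
a negative draw is a few percent for short exposures (see *Synthetic data*
below).  The likelihood deliberately keeps the untruncated normal; the
generator clips forward draws at zero and reports the clipped fraction.

### Covariates and standardization

The day-level design contains a linear day-of-year term, its square, habitat
cluster indicators, and optionally daily weather (temperature,
precipitation, wind), preceding-winter summaries (frost days, winter
precipitation), land-use fractions in a 200 m radius (arable, grassland,
forest, water), plant-survey covariates (herb/tree richness, community-mean
Ellenberg indicators), and interactions of the year index with day terms
and land-use fractions.  Seven named specifications (null, basic, weather,
habitat, landuse, landuse_interactions, final) select subsets; their
location-parameter counts are 5, 8, 13, 15, 12, 16 and 23.

All covariates are standardized to the build set, with three exceptions:
the year index (kept as small integers so log λ is a per-year rate), the
land-use fractions (already on a meaningful [0, 1] scale), and indicator
dummies.  The squared-day column is the square of the *standardized* day
number (then itself standardized): with that convention a negative
coefficient produces a dome-shaped seasonal profile peaking near the mean
sampling day, which is the shape the quadratic is there to capture.
Standardization records are stored with the design and replayed exactly
when projecting.

The year index defaults to the calendar offset from the first observed year
(1989 → 0, 2016 → 27); a consecutive-rank coding (gap years collapsed) is
available via `year_coding="consecutive"`.

## Sampler

Fitting is by adaptive Metropolis-within-Gibbs, written for this model:

* Scalar random-walk updates for the intercept, each regression direction,
  each site effect, and √v; an exact Gibbs draw for σ_site (under the
  Uniform(0, 10) prior on the sd, the precision's full conditional is a
  truncated gamma); and a translation sweep moving mass between the
  intercept and the mean of the site effects without changing the linear
  predictor (the predictor-invariant direction that otherwise mixes slowly).
* **Internal orthogonalisation.**  Design columns (year included) are
  centered and QR-orthogonalised in two groups — columns constant within
  every sample, and day-varying columns.  Random walks operate on the
  orthogonal coordinates and are mapped back exactly to model-scale
  coefficients for the prior and for recording, so the sampled posterior is
  exactly the posterior of the original parameterisation.  This removes the
  near-collinearity of day with year × day and of day with day², which
  otherwise keeps R̂ high for those coefficients.
* **Unidentified columns** (zero variance — e.g. a cluster dummy when no
  site of that cluster is present) contribute nothing to the likelihood;
  their coefficients are drawn i.i.d. from the prior, which is the exact
  full conditional.
* **Likelihood bookkeeping.**  The likelihood depends on the day-level
  predictor only through per-sample sums S1 = Σe^η and S2 = Σe^{2η}.
  Moves along sample-constant directions rescale S1/S2 by per-sample
  factors; only day-varying moves touch the day grid.  This makes a
  full-scale fit (≈1600 catches, ≈17000 exposure days) run in well under a
  minute per protocol below.

Priors: Normal(0, sd 10³) on all location parameters; Uniform(0, 10) on
σ_site and √v.  Proposal scales adapt toward 44% acceptance during burn-in
only (batches of 50), preserving detailed balance afterwards.  Chains are
initialised dispersed (intercept near log mean daily mass ± noise).

The default protocol is 3 chains × 6000 iterations, 1000 burn-in, keep
every 5th — a desk-scale protocol chosen because every convergence
diagnostic we track (R̂ ≤ 1.02 on all parameters, stable DIC) is already
satisfied there; the full production protocol (3 × 24000, 4000 burn-in,
thin 10) is a parameter change.

### Diagnostics

R̂ is the classic (non-split) Gelman–Rubin factor; convergence threshold
1.02.  DIC uses pD = var(deviance)/2 by default (the convention of common
Gibbs-sampler front-ends); pD = D̄ − D(θ̄) is available via
`dic(method="mean")`.  R² is the squared correlation between observed and
posterior-mean log biomass over positive catches.  Empirical p-values are
two-sided tail fractions of the posterior, draws at exactly zero counting
to neither side.

## Projections

All projections are per posterior draw over a day-of-year window (default
1 April–30 October = days 90–302, Jan 1 = 0, non-leap).  Site effects are
integrated out through the log-normal mean factor e^{σ²_site/2}
(population-level curve); `site_effects="zero"` gives a typical-site curve.
The weighted decline is 100·(1 − Σz_to/Σz_from) per draw; the peak-day
decline locates the maximum of the start-year curve per draw and takes the
ratio there.  When year × day interactions are absent the seasonal sum
factorises and both equal 100·(1 − e^{logλ·Δk}) exactly, which is tested to
1e-12.  The no-trend counterfactual zeroes log λ in every draw while
covariates follow supplied early/late values; with a single changing
covariate it reduces to the marginal effect e^{β·δ}.

## Weather preparation

Station series decompose additively as value = f_k(year) + f_t(day) +
r(year, day) + a·altitude + residual: f_k a penalized B-spline over years
(10 segments), f_t a periodic penalized B-spline over day-of-year (20
segments), both with second-difference penalties and smoothing chosen by
GCV (coordinate-wise grid 10⁻²…10⁶); r is a per-year periodic smooth of the
daily station-mean residuals — one of several defensible readings of an
"annual anomaly" term; it is isolated in one function and easily replaced.
Residuals get a separable exponential(space) × exponential(time) covariance
fitted by weighted least squares to the binned empirical spatio-temporal
variogram (weights √pair-count).  When the structured model barely improves
on a flat variogram (relative weighted-SSE gain < 1%) or the partial sill
is under 5% of the total, the field is reported as pure nugget — finite
samples of white noise otherwise yield arbitrary, unidentified ranges.

Interpolation to trap locations is ordinary kriging of same-day residuals
(weights sum to one; exact at stations when the nugget is zero) plus the
deterministic components at the target; stations beyond 100 km are
excluded and an empty neighbourhood is an error.  Frost days count strictly
sub-zero daily means over the preceding November–February (120 days,
non-leap); winter precipitation sums the same window; both demand complete
coverage and list missing days.

## Land use and habitat covariates

Cover fractions surveyed at two epochs are interpolated linearly on the
logit scale — identical to the prediction of a saturated two-point binomial
GLM with logit link, which serves as the test oracle.  Exact 0/1 fractions
are shrunk by 1/(2·1000) before the transform (moves values < 0.0005,
keeps the logit finite).  Targets outside the epochs extrapolate with a
warning.  Ellenberg indicator means are arithmetic means over species,
skipping species without a value per indicator.  Richness trends come from
a Poisson log-link mixed model with a site random intercept, fitted by
Laplace-approximate MAP (statsmodels' Bayesian mixed GLM); the function
reports the year slope, its sd, and a residual-deviance/df dispersion
diagnostic flagged above 1.5 — herb richness in data of this kind is
overdispersed and a negative-binomial variant is deliberately out of scope,
the diagnostic making the misfit visible instead.

## Synthetic data

The generator is the forward direction of the fitted model plus a campaign
layer, and its defaults are the study conditions: 63 sites, 96 site-years
over 1989–2016 (each site sampled at least once, extras spread randomly up
to 4 years per site), habitat clusters drawn 19:41:3, season window
March–October (days 59–303) with each site-year trapping a random
sub-window (up to 60 days of jitter at each end, giving mean exposures near
180 days), and contiguous exposure intervals whose lengths are integer
draws from a normal truncated at 1 day, the parent moments solved
numerically so the *truncated* law has mean 11.2 and sd 6.3 days.  Catches
are drawn from N(μ_j, σ²_j) and clipped at zero; with the default v = 0.870
about 6–9% of draws clip (dominated by one-to-few-day exposures), the
fraction is recorded in the truth file, and because the per-catch
coefficient of variation is independent of the mean the clipping distorts
the intercept slightly but not the trend — trend recovery simulations show
bias ≈ 2·10⁻⁴ on log λ.

Covariates are structural, not meteorological: daily temperature /
precipitation / wind as seasonal sinusoids with AR(1) noise; land use from
a per-site Dirichlet at two epochs, logit-interpolated to sampling years;
Ellenberg means normal around cluster-specific centres; richness Poisson
with a mild log-linear decline.  Truth coefficients are expressed on the
standardized scale of the generated design itself, so refits recover them
on the same scale.  What passing recovery tests therefore shows is that
the estimation machinery inverts the stated model at realistic sizes and
noise levels — not that real campaigns satisfy the model (real data bring
trap outages, weather-dependent catchability, and non-normal aggregation
error that the generator does not emulate).

## Numerical choices and degenerate inputs

Inclusive interval convention: a one-day catch has length 1; total exposure
is Σ(τ₂ − τ₁ + 1).  Empty sample collections, reversed intervals, negative
masses, duplicate (site, year, τ₁) keys, single-station weather networks,
all-zero richness counts and non-simplex cluster probabilities are errors,
not warnings.  The GCV solves add a 10⁻¹⁰ ridge; kriging systems a 10⁻¹⁰
diagonal jitter.  Every randomized entry point takes an explicit seed and
is bit-reproducible given it; an absent seed raises.

## Known limitations

Interpolation uncertainty from the weather stage is not propagated into
the biomass likelihood; the observation model admits (and clips) negative
masses rather than truncating the likelihood; the anomaly term r(year, day)
is an interpretation; the richness GLMM is MAP/Laplace, not full posterior;
habitat-cluster stratified refits and repeated-sites subsets are expressed
by filtering the input tables rather than by dedicated functions.
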