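# biomasstrend

Hierarchical Bayesian trend estimation for flying-insect biomass measured
with malaise traps.

## The problem

Long-term malaise-trap monitoring produces *interval-aggregated* data: each
bottle accumulates the wet biomass (grams) of everything caught over a
multi-day exposure interval, and intervals differ in length within and
between seasons.  Log-transforming the totals is wrong — the quantity that
adds up across days is biomass, not log-biomass — and daily covariates such
as temperature cannot be attached to a multi-day total directly.
`biomasstrend` implements the latent daily-biomass observation model that
solves both problems, plus everything around it: covariate preparation
(spatio-temporal weather interpolation, land-use interpolation, plant-survey
summaries), MCMC fitting with convergence and model-comparison diagnostics,
decline projections, and a synthetic-campaign generator with known ground
truth so every stage is testable without any external data.

It is aimed at ecologists and biostatisticians analysing trap networks of
the kind run across European protected areas since the late 1980s: tens of
sites, a handful of seasons each, catches emptied roughly every 11 days from
March to October.

## The model

The mass of catch *j* at site *s* in year *k*, exposed over days
τ₁…τ₂ (inclusive), is

```
m_j ~ Normal(μ_j, σ²_j)        μ_j = Σ_t z_t        σ²_j = Σ_t σ²_t
z_t = exp(y_t)                 y_t = c + log(λ)·k + x_t'β + u_s
σ²_t = exp(2y_t + v)(exp(v) − 1)
```

with site random intercepts `u_s ~ Normal(0, σ²_site)` and `v` the residual
variance of daily log-biomass, so that σ²_t is the exact method-of-moments
variance of a log-normal with log-mean y_t and log-variance v.  `log λ` is
the annual trend: `100·(1 − e^{log λ})` is the percent annual decline.  A
ladder of specifications (`null`, `basic`, `weather`, `habitat`, `landuse`,
`landuse_interactions`, `final`) controls which covariates enter `x_t`.
Fitting is by adaptive Metropolis-within-Gibbs with vague priors (flat
normals on location parameters, Uniform(0, 10) on σ_site and √v);
diagnostics include the Gelman–Rubin R̂, DIC with pD = var(D)/2, R², and
empirical two-sided posterior p-values.

## Worked example

```python
from biomasstrend import BiomassTrendModel
from biomasstrend.simulate import GeneratorConfig, TruthParams, generate_dataset

truth = TruthParams(
    c=2.450, log_lambda=-0.063,
    coefficients={"day": -0.100, "day2": -0.447,
                  "cluster2": 0.420, "cluster3": 0.332},
    sigma_site=0.334, v=0.870,
)
config = GeneratorConfig(n_sites=63, n_site_years=96,
                         years=tuple(range(1989, 2017)), truth=truth, seed=42)
samples, sites, covariates, record = generate_dataset(config)

model = BiomassTrendModel(samples, sites, spec="basic")
res = model.fit(seed=11)           # 3 chains x 6000, burn-in 1000, thin 5
print(res.summary().loc[["log_lambda", "day2"]].round(4))
peak = res.peak_decline(1989, 2016)
print(f"peak-day decline: {peak.decline_percent:.1f}% "
      f"[{peak.interval[0]:.1f}, {peak.interval[1]:.1f}]")
```

prints (about a minute on one CPU):

```
              mean      sd    2.5%   97.5%    P    rhat
parameter
log_lambda -0.0673  0.0027 -0.0728 -0.0622  0.0  1.0020
day2       -0.4573  0.0233 -0.5023 -0.4100  0.0  0.9996
peak-day decline: 83.8% [81.3, 86.2]
```

The posterior recovers the generating values (`log_lambda` −0.063, `day2`
−0.447), and the projected peak-season decline over the 27-year span
matches the closed form `100·(1 − e^{−0.063·27}) = 81.7%` within its
credible interval.

The same pipeline is scriptable from a shell:

```
biomasstrend simulate --seed 1 --sites 63 --out run/
biomasstrend fit      --data run/ --model basic --seed 2 --out run/fit/
biomasstrend project  --data run/ --fit-dir run/fit/ --window 04-01:10-30 --out run/proj/
```

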