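# vinebirds

Statistical pipeline for **avian predator-augmentation experiments in
vineyards**: point-count survey summarisation, a pooled-bootstrap null
test for treatment differences, and a binomial logit mixed model for
sentinel-prey removal — plus a synthetic-season generator so the whole
pipeline runs, and is tested, without field data.

The target design: each vineyard ("site") is split into a half provisioned
with songbird nest boxes (occupied mainly by Western Bluebirds, *Sialia
mexicana*) and a control half. Birds are surveyed by 30-minute point
counts (six 1-minute samples at 5-minute intervals, 85 m radius, five
points per half), and predation pressure is indexed by transects of five
immobilized sentinel larvae scored removed/present after exposure.

## The statistics

**Pooled-bootstrap treatment test.** Each response (species richness,
insectivore richness, and per-interval abundance of all birds, the focal
species, non-focal insectivores, omnivores, granivores) is reduced to six
replicate means per treatment (3 periods × 2 sites). The twelve values
are pooled, and a null distribution of "no treatment effect" differences
is built as

&nbsp;&nbsp;&nbsp;&nbsp;d*ᵦ = mean(x*₁…x*₆) − mean(y*₁…y*₆),  b = 1…B,

both resamples drawn with replacement from the pool (B = 1000, m = 6).
The observed nestbox − control difference gets the add-one empirical
P-value p = (1 + #{|d*| ≥ |d_obs|}) / (B + 1), with floor 1/(B+1) ≈ 0.001.

**Sentinel-removal GLMM.** Removals y_t out of 5 per transect follow

&nbsp;&nbsp;&nbsp;&nbsp;y_t | u_b ~ Binomial(5, logit⁻¹(x_t′β + u_b)),  u_b ~ N(0, σ_b²),

with treatment (control / random nest-box / active nest), site, and
optionally their interaction as fixed effects and a site × vineyard-half
random intercept. The marginal likelihood is maximised with adaptive
Gauss–Hermite quadrature (order 15 default; Laplace = order 1 available);
nested models are compared by likelihood-ratio χ², and the three pairwise
treatment contrasts carry Wald z with single-step (max-|Z| multivariate
normal), Bonferroni, or no adjustment. The fitter is validated against
lme4::glmer reference values frozen in the test suite.

## Worked example

Simulate a season at the study design and analyse it (the numbered
drivers under `analysis/` chain these steps and write tables under
`results/`):

```sh
python analysis/01_simulate_season.py 1
python analysis/04_sentinel_glmm.py 1
```

prints, for seed 1:

```
mean larvae removed (of 5) per group:
                count  mean
group
active_nest         7  4.71
control            10  1.60
nestbox_random     10  3.40

treatment effect: chi2 = 20.8, df = 2, P = 3e-05 (sigma_b = 0.00)

pairwise contrasts (logit scale, single-step adjusted):
                        pair  estimate    se     z  p_adjusted      adjust
    nestbox_random - control     1.519 0.431 3.524       0.001 single_step
       active_nest - control     3.552 0.790 4.496       0.000 single_step
active_nest - nestbox_random     2.032 0.790 2.573       0.025 single_step
```

Read: larvae on transects near active nests disappear far more often than
on control transects (z = 4.5 on the log-odds scale), random nest-box
transects sit in between, and dropping the 3-level treatment from the
model costs a deviance of 20.8 on 2 degrees of freedom — strong evidence
that provisioning nest boxes increases pest removal. The same library
calls are available programmatically:

```python
from vinebirds import SimConfig, simulate_sentinel, fit_binomial_glmm, ModelSpec

transects = simulate_sentinel(SimConfig(seed=1))
fit = fit_binomial_glmm(transects, ModelSpec(fixed=("treatment", "site")))
print(fit.summary())
```

A `vinebirds` console command exposes the same pipeline
(`simulate`, `summarize`, `boot-test`, `sentinel-fit`, `distance`,
`energetics`, `report`), each run writing a JSON manifest with config
hash, input digests and master seed.

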