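# Methods

`vinebirds` re-implements, as a tested pipeline, the statistical analysis
of a predator-augmentation field experiment: two organic vineyards
("sites"), each split into a nest-box treatment half and a control half,
with avian point counts, nest monitoring, and a sentinel-prey predation
assay. This note records the models, the parameter choices, and the
design decisions taken where the original analysis left them open.

## Survey summaries

A 30-minute observation sample at one point on one visit consists of six
1-minute counts taken at 5-minute intervals within an 85 m radius. Two
per-sample statistics are computed:

- **richness** — distinct species across the six intervals, optionally
  restricted to one dietary guild (insectivore I, omnivore O, granivore G);
- **per-interval abundance** — total counted individuals matching a
  filter (all species, one guild, one species, or a guild minus one
  species) divided by 6.

Per-sample statistics are averaged with equal weight per sample within
each treatment × site × period cell, giving 3 periods × 2 sites = **6
replicate means per treatment** per response. The season is partitioned
into early (22 Apr–22 May), middle (23 May–20 Jun) and late
(21 Jun–19 Jul) phenology periods; the boundaries are configurable.
An alternative weighting — pooling raw intervals across points — would
weight points by their number of usable visits; we average per-sample
statistics equally and keep cells with missing visits as averages over
the samples present (no imputation). Sighting tables count every
individual in every interval ("sightings", not unique birds; repeated
1-minute samples cannot deduplicate individuals).

## Pooled-bootstrap treatment test

For each response the 12 replicate means are pooled; B = 1000 bootstrap
means of size m = 6 (drawn with replacement) are paired with a second,
independent set of B such means and differenced elementwise, forming a
null distribution of mean differences under no treatment effect. The
observed nestbox − control difference is referred to this distribution
with the add-one rule p = (1 + #{|null| ≥ |obs|})/(B + 1), so p is a
multiple of 1/(B+1), never 0, and floors at ≈0.001 for B = 1000. Ties
count as exceedances; an observed difference of zero yields p = 1.
Sidedness defaults to two-sided on |difference|; a signed one-sided mode
is provided since the original sidedness is not recoverable. Each
response draws from an independent substream keyed by (master seed,
CRC-32 of the response name), so adding a response never perturbs
another's result. The pooled values are sorted before drawing, which
leaves the bootstrap law unchanged but makes the realized null invariant
to group labelling.

The test is approximate at n = 6 + 6: simulation under a no-effect
generator (see below) puts the type-I error near nominal at 0.01/0.05 and
mildly above at 0.10 (~0.11–0.12 intrinsic to the pooled scheme at this
sample size); the calibration study in `vinebirds.calibration` recomputes
this on demand.

## Binomial logit mixed model for sentinel removal

Each transect exposes five immobilized larvae; the response is the count
removed out of 5. The model is

    y_t | u_b ~ Binomial(n_t, logit⁻¹(x_t'β + u_b(t)))
    u_b ~ N(0, σ_b²)

with categorical fixed effects among {treatment (control / random
nest-box / active nest), site, treatment × site} and one random intercept
per spatial block. "Spatial block" is read as site × vineyard half
(4 blocks in the original design): transect-level intercepts are
unidentifiable with one binomial(5) observation each, and a per-transect
overdispersion intercept can be had by passing a transect-id block
column. Estimation is maximum marginal likelihood; the 1-D random-effect
integral per block is evaluated by **adaptive Gauss–Hermite quadrature**
(default order 15; order 1 is exactly the Laplace approximation and is
exposed as a comparability mode, since lme4-style fitters default to
Laplace). Each block's integrand is recentred at its conditional mode
(damped Newton) and rescaled by the curvature there. σ_b is optimised on
the log scale; after optimisation the fit is profiled against the exact
σ_b = 0 binomial GLM and snaps to the boundary when the marginal
likelihood is not improved (at σ_b = 0 the marginal likelihood equals
the plain binomial likelihood exactly, by construction). The optimiser
is a short derivative-free sweep (Nelder–Mead) followed by a BFGS polish;
covariance is the inverse observed information (central-difference
Hessian), with the GLM information used at the boundary. Complete
separation (a treatment group all-0 or all-5) raises an error naming the
group; optimizer failure is flagged on the returned fit, never silent.

Cross-checks in the test suite: coefficients, standard errors, σ_b and
the deviance gap agree with lme4::glmer (nAGQ = 25) on two frozen fixture
datasets to ≈1e-5 (glmer reports log-likelihood relative to the saturated
model; the comparison adds the saturated binomial term back); the
σ_b = 0 path agrees with a brute-force independent-binomial ML fit to
< 1e-6; the log-likelihood moves < 1e-6 between quadrature orders 15
and 25.

**Likelihood-ratio tests** compare nested fixed-effect specifications by
deviance difference against χ² with df = the parameter-count difference;
dropping the 3-level treatment costs df = 2. ML (not REML-like)
estimation is used throughout for this reason.

**Pairwise contrasts** are the three treatment differences on the logit
scale, averaged over site levels with equal weight when site terms are
present, with Wald z = estimate/SE. The default multiplicity adjustment
is **single-step**: p = P(max_k |Z_k| ≥ |z|) under the joint normal law
of the contrasts with correlation taken from the fitted covariance,
evaluated by seeded Monte-Carlo (2×10⁵ draws); Bonferroni and unadjusted
modes are available. Adjusted p is clipped below by the unadjusted p.
Which adjustment the original analysis used is not recoverable; the
single-step default reproduces the qualitative pattern of a mid-size
z (~2.2) landing near p ≈ 0.07 where Bonferroni would give ≈0.08.

## Foraging-distance profiles

Focal-species detections in the nest-box half carry distances from the
observation point, which is an active nest there. Distances are binned
right-inclusively into 0–20, 21–42, 43–64 and 65–85 m by default (the
text anchors "intermediate" at 21–42 m and "far" at >65 m; the exact
original binning is not printed, so edges are configurable). Records
without a distance (heard-only) are excluded from profiles and their
count reported. The far-field fraction is the share of detections in the
outermost bin.

## Energetics

Daily arthropod demand of a nest is linear in occupants:
(78 g/5) × n_nestlings + 23 g × n_adults, i.e. 15.6 g/day per nestling and
23 g/day per adult, giving 124 g/day for a pair with a brood of five. The
65 kJ/day nestling energy figure is carried as metadata only; the implied
kJ→g conversion is never printed and is not exposed.

## Synthetic-data generator

The generator is the package's stand-in for the undeposited field data;
its defaults are the study conditions, not tuning knobs.

- **Point counts.** Species counts per 1-minute interval are independent
  Poisson with per-species rates; the nest-box half multiplies each rate
  by a species multiplier. Rates are the published per-species season
  totals divided by 180 observation intervals — the divisor that
  reproduces the published per-interval means (e.g. focal nest-box
  313/180 = 1.74 against the printed 1.82) — with the focal species
  pinned directly to the printed 0.18 (control) and 1.82 (nest-box)
  birds/interval (multiplier ≈ 10.1). Species never sighted in the
  control get a quarter-sighting continuity floor so a positive nest-box
  rate remains expressible as baseline × multiplier. Distances are
  uniform on [0, 85] m. A negative-binomial option adds overdispersion;
  the default is pure Poisson because only means are published.
- **Sentinel transects.** Per site: 5 control transects (control half),
  5 random + 4 or 3 active-nest transects (nest-box half). Removals are
  Binomial(5, logit⁻¹(β_group + u_block)) with u_block ~ N(0, σ_b²),
  σ_b = 0.5 by default. The β defaults are the conditional logits of the
  published group means (1.2, 2.9, 4.14 of 5); under σ_b > 0 the
  *marginal* means are slightly attenuated toward 2.5 (≈1% at these
  values), which the moment tests account for by silencing the block
  effect when checking the calibration.
- **Nests.** Box-pair occupancy 0.761 by the focal species; clutch sizes
  4/5/6 with probabilities 0.27/0.55/0.18 (mean 4.91).

What the generator does **not** emulate: interval-to-interval dependence
(the same bird re-sighted — unknowable from published information, so
intervals are independent, which understates richness saturation and
between-visit variance), weather-driven missing visits, within-season
population dynamics, and distance-dependent detectability (distances are
uniform, so simulated distance profiles reproduce only the shape of the
reporting, not the published near-nest concentration). Because the rates
embed the published between-area totals for *every* species, simulated
seasons carry small built-in guild differences that the idealized Poisson
replicate variance can flag as significant even though the field test did
not; passing tests therefore demonstrate correctness of the machinery
under the stated laws, not field-data conclusions. All draws come from
one seeded generator per dataset (sentinel and nest streams offset by
fixed spawn keys), and identical configs give byte-identical CSV output.

## Calibration studies (`vinebirds.calibration`)

- **Type-I error**: 500 seasons simulated with all multipliers forced to
  1, tested at B = 999; the rejection rate at α ∈ {0.01, 0.05, 0.10} is
  compared with nominal within binomial Monte-Carlo error.
- **Wald coverage**: 500 synthetic sentinel experiments at the study's
  group means with the per-site transect plan scaled to 20 sites
  (40 blocks, 280 transects) so the asymptotic Wald approximation is
  meaningful at the stated runtime; coverage of 95% intervals for the two
  treatment logits is compared with 0.95 within Monte-Carlo error.
  (At the original 4-block size, interval coverage is not a meaningful
  check of the fitter.)
- **σ_b = 0 oracle** and **quadrature stability** as described above.

Problem sizes throughout (500 replicates, 20-site coverage designs,
B = 999–1000) were chosen to make Monte-Carlo error small relative to
the quantities checked while keeping each study in the tens of seconds
to low minutes on one core.

## Known limitations

- The mixed-model engine is deliberately narrow: binomial/logit, one
  random-intercept grouping, categorical fixed effects only.
- Wald intervals show the usual mild small-sample undercoverage (~1
  point at the 20-site design); profile-likelihood intervals are not
  implemented.
- The pooled-bootstrap test is the study's own procedure and inherits
  its small-sample approximation; no parametric fallback is provided
  because the original analysis rejected ANOVA assumptions.
- No detection-probability or distance-sampling correction is applied
  anywhere (none was applied originally).
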