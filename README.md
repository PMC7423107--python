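# reefbarrens

Bayesian spatio-temporal analysis of urchin-barrens presence in benthic
AUV imagery.

## The problem

On temperate rocky reefs invaded by the range-extending long-spined sea
urchin, overgrazing converts kelp beds into bare-rock "barrens". Marine
monitoring programs photograph the seafloor along repeated AUV transects
and score each image as barren or not. The scientific questions are
whether a no-take reserve (NTR) resists barren formation, how fast
barrens are expanding, and how depth and seafloor complexity (rugosity)
shape where barrens occur — while accounting for the strong spatial
patchiness of barrens and their persistence from year to year.

`reefbarrens` implements the full analysis as a tested, reusable Python
package, exercised end-to-end on synthetic surveys with known truth:

- **terrain** — vector ruggedness measure (VRM) from a bathymetry raster
  (Horn slope/aspect on 3×3 windows, unit-normal resultant over an
  n×n neighbourhood; default 3 cells), logit transform and covariate
  standardisation, nearest-cell raster sampling, ESRI ASCII grid I/O.
- **imagefilter** — the image-level rules: an image is a barren when
  more than 50 % of it is bare rock *and* urchins are present in it or in
  an adjacent (>50 % bare-rock) image of the same transect-year; >50 %
  sand images are excluded as non-reef; each transect-year is subsetted
  to every fifth image; covariates are joined and standardised.
- **stmodel** — three nested Bernoulli models of barren presence
  y(sᵢ,t) ~ Bernoulli(p(sᵢ,t)), logit p = X(sᵢ,t)β + z(sᵢ,t):
  M1 (fixed effects only), M2 (+ a Matérn ν=1 spatial field per year),
  M3 (+ stationary AR(1) dependence of the yearly fields, the separable
  space-time model), with marginal likelihoods for model comparison.
- **summaries** — odds ratios exp(β) and percent changes
  (exp(β)−1)·100, conditional probability curves from joint posterior
  draws with random effects set to zero, posterior model probabilities
  under equal prior weights, percent-barrens tables with binomial SEs.
- **synthetic** — the generative model itself: grid-pattern survey
  designs over four sites (one NTR, surveyed in one extra year),
  synthetic bathymetry, latent AR(1)×Matérn fields, and scored image
  attributes arranged so the classification rules have real work to do.
- **pipeline / cli** — a reproducible end-to-end run with config files,
  seeds, provenance metadata and a checksum manifest.

## The model

The full model M3 is a separable space-time Bernoulli model on the logit
scale:

    y(sᵢ,t)   ~ Bernoulli(p(sᵢ,t))
    logit p   = X(sᵢ,t) β + z(sᵢ,t)
    z(·,t)    = φ z(·,t−1) + ω(·,t),   ω(·,t) ~ N(0, Σ(ρ, σ²))
    z(·,1)    ~ N(0, Σ(ρ, σ²) / (1−φ²))        (stationary start)

with Matérn (ν = 1) spatial correlation H(d) = κd·K₁(κd), κ = √8/ρ, so
the range ρ is the distance at which correlation falls to ≈0.1. Fixed
effects are, in order: intercept, NTR, year, logit-rugosity, depth,
depth², NTR×year (depth, depth² and logit-rugosity centred and scaled).
Hyperpriors are Gaussian on log ρ, log σ and log((1+φ)/(1−φ)); each
β ~ N(0, s²).

Inference: M2/M3 use a Laplace-within-importance-sampling engine (the
latent Gaussian block is integrated by a Laplace approximation whose
Newton steps exploit the per-site Kronecker years×points structure; the
2–3 hyperparameters are importance-sampled around their posterior mode),
which yields the marginal likelihood as a by-product. M1 is sampled with
an affine-invariant ensemble MCMC (`emcee`, two independent ensembles
for honest convergence diagnostics) and its evidence estimated by
iterative bridge sampling.

## Worked example

```sh
reefbarrens demo --seed 0 --out runs/demo
```

simulates a small four-site survey (one NTR; years 2011/2013/2016, NTR
also 2014) from the default generative truth, runs classification,
filtering and subsetting, fits M1/M2/M3 and writes all summaries. From
`runs/demo/model_comparison.csv`:

```
model,log_marginal_likelihood,posterior_probability
M1,-170.47,7.98e-12
M2,-148.10,0.0415
M3,-144.96,0.9585
```

The evidence decisively favours spatial dependence (M2 over M1 by ~22
log units) and prefers the full space-time model. From
`summary_M3.csv`, the dependence block (this small demo uses ~290
images, so intervals are wide):

```
range_m,                mean 18.7,  95% CI [ 9.6, 32.8]
spatial_sd,             mean  2.1,  95% CI [ 1.0,  3.9]
temporal_correlation,   mean  0.75, 95% CI [0.49, 0.91]
```

against generative values of 17.1 m, 3.4 and 0.73: short-range spatial
patchiness and strong year-to-year persistence are both recovered. On
the odds scale, a reserve coefficient of −3.107 corresponds to
`odds_ratio(-3.107) = 0.045`, i.e. a 96 % reduction in the odds of
barrens inside a reserve, and a year coefficient of 0.277 to odds
growing by 31.9 % per year — the arithmetic used to report effects:

```python
>>> from reefbarrens.summaries import odds_ratio, pct_change_odds
>>> odds_ratio(-3.107), pct_change_odds(-3.107)
(0.04473..., -95.52...)
>>> odds_ratio(0.277), pct_change_odds(0.277)
(1.3191..., 31.91...)
```

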