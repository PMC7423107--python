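# Methods

This note documents the statistical model, the synthetic-data generator,
the inference engines, numerical choices, and known limitations of
`reefbarrens`.

## Model

Barren presence per image is Bernoulli with a logit-linear predictor

    logit p(sᵢ,t) = X(sᵢ,t) β + z(sᵢ,t).

The latent field z is separable in space and time: spatially a Matérn
field with smoothness ν = 1 and correlation H(d) = κd K₁(κd),
κ = √8/ρ — under this convention the *range* ρ is the distance at which
correlation has decayed to ≈0.1 (H(ρ) ≈ 0.14 exactly; the convention is
the standard one for this Matérn family) — and temporally a stationary
AR(1) with one-year-step correlation φ, started from its stationary
distribution. σ is the sd of the yearly innovations, so the stationary
marginal sd of z is σ/√(1−φ²). Survey years are not consecutive
(2011, 2013, 2014, 2016); lag-k correlations are φᵏ in calendar years.

Fixed effects (reporting order): intercept, NTR (binary), year (integer
years since the first survey), logit-rugosity, depth, depth², NTR×year.
Depth² is squared on the raw scale and then standardised as its own
column; depth, depth² and logit-rugosity are centred/scaled by the
*analysis sample's* mean and sd (recorded in a sidecar file so
prediction grids reuse identical transforms). Year coding starts at the
first survey year; this affects only the intercept's interpretation.

Nesting: M2 is M3 with φ = 0; M1 is M2 with the spatial field removed.
Models are compared by marginal likelihood under equal prior weights.

### Priors

Gaussian on transformed scales: log ρ ~ N(log 20, 1²),
log σ ~ N(0, 1²), log((1+φ)/(1−φ)) ~ N(0, 1²), β ~ N(0, 10²) each.
These are deliberate defaults for a survey whose image spacing is metres
and whose dependence is expected at tens of metres; all are user
configuration (`PriorSpec`), and sensitivity to them is a user knob, not
a hidden constant. Because the priors of the original analysis of the
real surveys are not public, exact numerical reproduction of the real
data coefficient table is *not* claimed anywhere in this package.

## Image-level rules

* Barren ⇔ bare rock > 50 % (strict) AND urchins present in the image,
  or in the immediately preceding/succeeding image of the same
  transect-year provided that image is also > 50 % bare rock.
  Adjacency never crosses transects or years. Classification runs on
  the full image series, before any subsetting.
* Non-reef exclusion: sand > 50 % (strict).
* Subsetting: every 5th image per transect-year, anchored at the first
  image of the (already sand-filtered) series. Pipeline order is
  classify → filter → subset → join; a regression test pins it.
* Images without underlying rugosity mapping (nodata cells) are dropped
  and counted.

Both 50 % cut-offs are read as strict inequalities; the original scoring
was visual, so behaviour exactly at the boundary is a convention.

## Terrain

VRM: per-cell unit surface normals from Horn's 8-neighbour finite
differences (the common GIS default; the originating toolchain does not
document its gradient operator), resultant length |R| over the n×n
neighbourhood (default 3), VRM = 1 − |R|/n². Cells whose effective
stencil (gradient window + neighbourhood) touches nodata or the grid
edge are nodata — mirroring the exclusion of unmapped survey area.
Depth sign (positive down) cancels out of VRM. Raster sampling is
nearest-cell, not bilinear: VRM is a neighbourhood property and
interpolation would mix scales. Logit-rugosity clips into
[ε, 1−ε], ε = 10⁻⁶, before log(v/(1−v)).

## Synthetic-data generator

The generator is the package's study system, not a fixture; its defaults
define the simulated survey conditions:

* **Design.** 4 sites ~200–300 m apart (far beyond the ~17 m range, so
  sites are effectively independent), one NTR. Per site, 3 parallel
  98 m transect lines 12 m apart; raw image spacing 0.4 m so that
  every-5th subsetting leaves images 2 m apart — well inside the
  correlation range. Years 2011/2013/2016 everywhere, 2014 at the NTR
  only. After subsetting this yields ~150 analysis points per site,
  ~600 point-years at the NTR, ~1 850 analysed point-years in total.
  The real survey's transect geometry is not public; these defaults are
  chosen to reproduce the short-range-correlation regime, not the real
  geometry. The full real-survey scale (~20 000 images) is reachable
  through `DesignConfig`, but no test requires it.
* **Bathymetry.** Smoothed Gaussian field rescaled to ~5–45 m depth
  plus localized high-frequency "rough patches", so VRM is right-skewed
  with mostly small values — the regime the logit transform addresses.
  An optional nodata margin exercises the unmapped-area exclusion.
* **Truth.** `REFERENCE_TRUTH` sets the generative parameters to the
  published posterior estimates for the monitored reserve system:
  β = (−7.475, −3.107, 0.277, 0.557, −0.280, −0.975, 0.065),
  ρ = 17.055 m, σ = 3.413, φ = 0.734. σ is interpreted as the
  *innovation* sd of the AR(1) recursion (the parameterisation written
  in the model equations above); grouped-AR1 implementations sometimes
  report the marginal sd instead, but the recovery experiments here are
  self-consistent under the stated reading.
* **Scored attributes.** Barren images draw bare rock in (55, 95) %;
  urchins appear in the image itself with probability 0.8, otherwise in
  an adjacent bare-rock image (falling back to the image itself when no
  such neighbour exists), so the classification's adjacency branch is
  genuinely exercised while the truth stays recoverable. Non-barren
  images stay ≤ 50 % bare rock; 5 % of them are > 50 % sand (excluded
  downstream). Sand is assigned independently per image — real sand
  patches are spatially clustered, so the generator does not test
  spatial structure in the exclusions, only their arithmetic.
* **What passing tests do not show.** The generator draws outcomes from
  exactly the fitted model family, scores images without observer
  error, and revisits identical image positions each year. Passing
  recovery tests therefore demonstrates the correctness of the
  implementation, not robustness to misclassification, positional
  error, or model misspecification in real imagery.

Determinism: every stochastic output is reproducible from
(configuration, seed); child streams are spawned per stage.

## Inference

### M2/M3: Laplace within importance sampling

For fixed hyperparameters θ (log ρ, log σ, and transformed φ for M3),
the latent Gaussian block u = (β, z) is integrated out by a Laplace
approximation: damped Newton/IRLS to the joint mode (the objective is
concave), then

    log p̃(y|θ) = ℓ(u*) − ½u*ᵀQu* + ½ log|Q| − ½ log|H|.

The latent grid is built per site as (merged spatial points) × (observed
years); nearly-coincident image positions (within 0.5 m) are merged to a
single spatial point, as the AR recursion requires. The prior precision
is then a per-site Kronecker product, and the Newton solves use a Schur
complement on β with per-site Cholesky factorisations — the cost is
O(Σ_g (m_g T_g)³) per evaluation instead of O(n³) for the full survey,
which is what makes the default-scale fit run in minutes. Covariances
are exact and dense: no mesh or sparse approximation; intended for up to
a few thousand latent sites.

The hyperparameter posterior ψ(θ) = log p̃(y|θ) + log p(θ) is optimised
(coarse deterministic grid seed, then two Nelder-Mead runs; the
surface can be ridged and a single simplex run can stall), a
finite-difference Hessian defines a multivariate-t proposal (df 7, scale
1.4), and 192 importance samples give: the marginal likelihood (the
self-normalised estimate with its delta-method SE), weighted
hyperparameter summaries, and 5 000 joint posterior draws (θ resampled
by weight; β|θ drawn from the Gaussian Laplace block, whose β-marginal
is the inverse Schur complement). The `fast` engine variant replaces
the importance sampler with the Laplace approximation over θ at its
mode — adequate for replicate experiments where only evidence
*orderings* matter.

Convergence reporting: optimiser success, Kish effective sample size of
the importance weights (flagged below 50), and the count of failed
inner Newton solves. The Laplace step's bias is not separately
quantified; the engine's accuracy is established against oracles in the
test suite (quadrature equivalence for the no-field model, nested-limit
agreement, evidence ordering under strong dependence).

### M1: ensemble MCMC + bridge sampling

The fixed-effects model is sampled by affine-invariant ensemble MCMC
(`emcee`) with a move mixture (stretch 0.5 / differential-evolution 0.4
/ snooker 0.1 — stretch keeps the tails calibrated, DE accelerates
mixing along correlated directions), initialised at the posterior mode.
Two *independent* ensembles are run so that the potential scale
reduction factor is computed between genuinely independent chains
(walkers within one ensemble interact, making walker-wise split-R̂
miscalibrated); chains are thinned by half the integrated
autocorrelation time τ before diagnosis. Convergence requires
R̂ < 1.01, ESS > 400, and chains longer than 30 τ (the length guard
protects the τ estimate; R̂ across ensembles is the primary check).
The evidence uses iterative (Meng–Wong) bridge sampling with a
moment-matched Gaussian proposal; its SE comes from batching. Posterior
separation (a mode coefficient beyond ±10) raises a warning; the prior
regularises the fit and it proceeds.

`log_marginal_likelihood(fit)` refuses a fit whose convergence flag is
down.

## Numerical choices

* Matérn at d = 0 is set to 1 exactly; a 10⁻⁶ diagonal jitter keeps
  spatial correlation matrices factorisable at extreme ρ.
* Exact duplicate coordinates in the generator are jittered by
  < cell/10 (deterministically from the seed) before building Σ.
* Newton stops at gradient ∞-norm < 10⁻⁶ or objective change < 10⁻⁸,
  with step halving; a failed solve marks that θ sample as zero weight.
* The finite-difference Hessian of ψ uses step 0.15 on the transformed
  scale, eigenvalue-floored at 10⁻² so the proposal never degenerates.
* Percent-barrens groups with k = 0 or k = n report SE 0 and are
  flagged in the log (the binomial SE is degenerate there).
* Standardisation uses the sample sd (ddof = 1); constant covariates
  are rejected rather than silently zeroed.

## Problem sizes used by the test suite

The suite runs the recovery experiment at the default scaled design
(~1 850 point-years; minutes), the coverage experiment as 200 replicate
M1 fits on a fixed ~700-row design with a shortened-chain engine, the
model-selection experiment as 20 replicates at n ≈ 600 with the fast
engine, and the Monte-Carlo identities at 500 replicates on a
single-transect design. The coverage design uses ~600 rows per
replicate: interval coverage is an asymptotic property, and the skewed
rugosity covariate undercovers noticeably at much smaller n even with
exact posteriors. These sizes are the package's own scaled
experimental design; the full-scale survey remains available through
configuration.

## Limitations

* O(n³)-per-site-year-block dense algebra: not intended beyond a few
  thousand latent sites.
* The Laplace approximation of the Bernoulli latent integral introduces
  a small evidence bias (conservative in the model comparisons tested,
  since it attenuates the latent models' evidence).
* Hyperparameter summaries rest on ≤ a few hundred importance samples;
  extreme posteriors (e.g. φ → 1) would degrade the t proposal before
  the diagnostics flag it.
* One NTR site only, as in the monitored system: the reserve effect is
  a single-site contrast by design.
* No spatial prediction surfaces over unsampled rasters, and no
  multi-scale rugosity optimisation; both are deliberate non-goals.
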