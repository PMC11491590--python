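# Methods

## Models

Two area-level models share one spatial prior.

**Incidence.** For area `i` with observed cases `y_i` and expected
counts `E_i` (computed externally by age-standardization against
national rates; they are an input, not something this package derives):

    y_i ~ Poisson(E_i * exp(mu + S_i)),      SIR_i = exp(mu + S_i).

Because `E_i` embeds the national rates, the national average sits at
SIR = 1, which is the reference for every probability statement below.

**Excess hazard (relative survival).** For area `i` and follow-up
interval `j`, with deaths `d_ij`, expected background deaths `e_ij`
from population life tables, and person-time `t_ij`:

    d_ij ~ Poisson(e_ij + t_ij * lambda_j * exp(S_i)),   EHR_i = exp(S_i).

This is the piecewise-constant excess-hazard Poisson approximation to
relative survival: the cancer-attributable hazard is proportional
across areas, interval baselines `lambda_j` absorb the national average
excess hazard, and the background contribution enters additively
through `e_ij`. It is the simplest member of the excess-hazard family
that yields an area-level ratio against a national reference of 1;
full relative-survival likelihoods and covariate effects are out of
scope.

**Spatial prior.** `S ~ N(0, Q^{-1})` with the Leroux CAR precision

    Q = (1/sigma2) * [rho * (D - W) + (1 - rho) * I],

`W` binary queen/rook adjacency, `D = diag(degree)`. We restrict
`rho ∈ [0, 1)`: the matrix is then strictly diagonally dominant, hence
positive definite, so the prior is proper without a sum-to-zero
constraint and isolated areas (degree 0, e.g. islands) are handled
naturally — their conditional prior is `N(0, sigma2 / (1 - rho))`. The
precision is stored sparse; realistic problems have ~2000 areas with
~6 neighbours each.

**Hyperpriors** (weakly informative, proper, standard for CAR disease
mapping): `sigma ~ half-Normal(0, 1)` on the standard-deviation scale,
`rho ~ Uniform(0, 1)`, `mu` and each `log lambda_j ~ Normal(0, 10^2)`.
`log(y!)` terms are kept in the likelihood so log-posterior values are
comparable across implementations.

## Sampler

Metropolis-within-Gibbs with random-walk proposals:

* `S`: single-site updates, vectorized by graph colouring. Greedy
  colouring partitions the areas into classes with no internal edges;
  sites within a class have mutually independent full conditionals
  given the rest, so one proposal/accept step per class is
  statistically identical to a sequential single-site scan but runs as
  numpy vector operations (a regular lattice needs 2 colours). The
  conditional evaluation is O(degree) via the sparse adjacency.
* `mu` (or each `log lambda_j`): scalar random walks.
* `log sigma2` and `logit rho`: scalar random walks with Jacobian
  corrections; the determinant term uses
  `log det[rho(D-W) + (1-rho)I] = sum_k log(rho g_k + 1 - rho)` with the
  eigenvalues `g_k` of `D - W` computed once per fit (dense `eigh`,
  acceptable to a few thousand areas).

Step sizes are adapted during burn-in only, by Robbins-Monro
(`log step += gamma_t (acc - 0.44)`, `gamma_t = min(0.5, 10/(t+10))`),
targeting 0.44 acceptance; adaptation then freezes so the retained
chain has the correct stationary distribution. Initialization is
moment-based: `mu = log(sum y / sum E)`, `S = 0`, `rho = 0.5`,
`sigma2 = 0.1`, `lambda_j = max(1e-4, (sum d - sum e)/sum t)`.
Acceptance rates per block are stored in the draws' metadata, with a
warning (not an error) outside [0.05, 0.95].

Defaults are `n_iter = 60 000`, burn-in 20 000, thinning 20 (2000
retained draws) — desk-scale but stable; the calibration experiments
use 20 000/10 000/10 (1000 retained), which the simulation studies show
is sufficient on a 10×10 lattice. Retained draws are stored on the
ratio scale (`exp(mu + S)` or `exp(S)`) because both the PPD and the
wave plot are defined against the ratio-scale reference of 1.

Convergence diagnostics are single-chain: bulk effective sample size
(via arviz) and split-half R-hat per area; a constant chain yields NaN
diagnostics rather than an error.

## Posterior summaries

* Point estimate: the posterior **median** of the ratio-scale measure.
* Intervals: **equal-tailed** 60% and 80% intervals using the type-7
  (linear-interpolation) quantile rule. Equal-tailed (rather than HPD)
  intervals keep the direct "probability 0.8 that the true value lies in
  this interval" reading for skewed ratio-scale posteriors and are
  order-preserving under the log transform, so 60% nests inside 80%.
* PPD: the proportion of draws strictly above 1, with draws exactly
  equal to 1 counted as half — removing directional bias in the
  measure-zero tie case.
* Classification: PPD ≥ 0.8 → "likely higher", ≤ 0.2 → "likely lower",
  else "uncertain". Published atlases word this as likely/unlikely to
  differ from the national average without printing cutoffs; 0.2/0.8
  are this package's explicit, configurable defaults.

## Visualization choices

* **Wave plot**: Gaussian KDE with Silverman's bandwidth on
  `log(draws)`, evaluated on a 256-point grid spanning the draw range
  plus three bandwidths each side. The density is computed on the log
  scale (so area = probability) and the axis ticks are placed at
  `log(r)` for ratio values `r ∈ {0.5, 0.75, 1, 1.33, 2}` (clipped to
  the grid) — a ratio-symmetric, configurable set. The overlay glyph
  shows the posterior median with 60%/80% bands; median is used
  consistently with the model outputs.
* **Colour ramp**: reversed diverging blue–yellow–red with anchors
  `#2C7BB6, #ABD9E9, #FFFFE0, #FDAE61, #D7191C`, the midpoint
  deliberately a pale yellow marking the national average. Estimates
  map through `t = clamp((log e - log lo)/(log hi - log lo), 0, 1)` so
  the gradient is linear in log-ratio; default breakpoints (0.5, 2.0)
  are symmetric as ratios, making `r` and `1/r` equally saturated.
* **Transparency**: with confidence `c = 2|PPD - 0.5|`, opacity is
  `alpha_min = 0.1` for `c ≤ 0.2`, 1 for `c ≥ 0.6`, linear between.
  The floor keeps faded areas visible; compositing is linear RGB over
  the neutral yellow, so maximal fade renders as the average colour.
  The functional form is this package's choice — production atlases do
  not publish theirs — and the encoding is on by default with an off
  switch.
* **Overviews**: percentage/count modes bin each group's point
  estimates into five colour classes equal-width in log-ratio between
  the breakpoints (open-ended outer bins absorb clamped values);
  boxplot mode reports min/q1/median/q3/max. All groups share one axis.

## Synthetic data

The generator emulates small-area registry data: a rook-adjacency
lattice (closed-form edge counts make tests exact), a Leroux CAR field
drawn exactly by dense Cholesky factorization of the precision (capped
at n = 2500 — fixture scale), heterogeneous expected counts
`E_i ~ Uniform(50, 200)` (mid-sized areas over a 5-ish-year window),
and Poisson observations. Default field parameters `rho = 0.8`,
`sigma2 = 0.25` give strong but not intrinsic spatial correlation and
SIRs mostly within [0.4, 2.5]. Survival scenarios use five follow-up
intervals, background rate 0.05/person-year, baseline excess hazard
0.1/person-year and 500 person-years per cell.

What the generator does **not** emulate: real administrative geography
and its extreme area-size skew, population age structure (expected
counts are drawn, not built from age tables), registry suppression of
sparse cells, data entry artefacts, or model misspecification. Passing
calibration checks therefore show the sampler and summaries are correct
*under the model family*, not that the model fits any particular
registry.

## Calibration experiments

`caratlas.experiments.coverage_experiment` simulates replicate datasets
(default: 10 replicates on the 10×10 scenario above), refits each
(20 000 iterations, 10 000 burn-in, thin 10) and pools 1000 area-level
checks of whether the equal-tailed 60%/80% intervals contain the true
SIR, plus per-replicate checks of whether the hyperparameters' 80%
intervals contain `rho` and `sigma2`. Replicate seeds derive
deterministically from one master seed via `SeedSequence`. At these
sizes the binomial Monte-Carlo noise on pooled coverage is roughly
±0.025 (2 SE, inflated somewhat by within-replicate correlation), so
observed coverage within ±0.04 of nominal is the consistent outcome.
`rho` is weakly identified on 100 areas — its posterior is wide — so
hyperparameter coverage is assessed against a loose ≥60% bound at 10
replicates.

## Numerical notes and limitations

* Draws are validated strictly positive; CSV floats are written with 6
  significant digits, so file round-trips are exact to that precision.
* Fits are bit-reproducible given (inputs, config, seed); a single
  chain is used, with split-half diagnostics instead of parallel chains.
* The eigen-decomposition of `D - W` is dense: fine to a few thousand
  areas, not beyond. No NUTS/HMC, no covariates, no zero-inflation, no
  multi-cancer shared components, no temporal trends.
* `rho → 1` (intrinsic CAR) is excluded by design; fits with posterior
  mass piled near 1 indicate the data want more smoothing than the
  proper Leroux prior allows.
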