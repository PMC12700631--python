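# Methods

## Model

Let `f(x)` be the structural function of a frozen source model — for the
reference models in this package, the linear predictor `x'theta_S_hat` of an
ordinary-least-squares or logistic-regression fit (callers include their own
intercept column; for binary responses the inverse-logit is applied
*after* the random effect, i.e. `P(y=1) = expit(beta * f(x))`).  Target
labels are modeled with a per-observation scalar random effect:

    continuous:  y_i = beta_i f(x_i) + sigma eps_i,  eps_i ~ N(0,1)
    binary:      y_i ~ Bernoulli(expit(beta_i f(x_i)))
    beta_i ~ Cauchy(delta, gamma), iid

The Cauchy family is exact, not heuristic: if `x ~ N_p(0, I)` then
`(x'a)/(x'b) ~ Cauchy(a'b/||b||^2, ||b||^{-2} sqrt(||b||^2||a||^2 - (a'b)^2))`
(`ratio_cauchy_params`, property-tested by Monte Carlo and
Kolmogorov-Smirnov).  `delta` measures the systematic rescaling between the
populations, `gamma` the residual dissimilarity; `gamma -> infinity` would
mean no usable link.  Estimating both parameters of a Cauchy law is
notoriously delicate (no moments exist), which motivates the fully
Bayesian treatment and the robust chain initialization below.

## Prior

`pi(delta, gamma[, sigma]) = N(delta | 1, 10^2) * logN(gamma | 0, 2^2)
[* logN(sigma | 0, 2^2)]`.  The prior centers on "populations are
identical" (`delta = 1`) but is diffuse: with even ~20 target observations
the likelihood dominates.  All five hyperparameters are exposed on
`PriorSpec`; sensitivity at the study's sample sizes is negligible because
the posterior is likelihood-dominated.

## Likelihood evaluation

Each observation contributes a one-dimensional integral over the latent
random effect.  Two numerical paths share one contract:

* **Reference path** (`loglik_term_continuous`, `loglik_term_binary`):
  adaptive Gauss-Kronrod (scipy's QUADPACK) at relative tolerance 1e-9
  with graded subdivision hints around the Cauchy spike.  The continuous
  integrand is first rewritten as a standard-normal-weighted expectation
  via `t = (beta - y/f)|f|/sigma`; since the standard normal density
  underflows to exactly 0.0 beyond |t| = 39 in IEEE doubles, restricting
  to [-39, 39] is *exact* in floating point (`integral_bound`).  The
  binary integrand has no Gaussian weight, so it uses the tan substitution
  `beta = delta + gamma tan(u)`, which absorbs the Cauchy measure into a
  uniform measure on (-pi/2, pi/2).  Absolute tolerance is set to zero on
  purpose: deep-tail terms can be far below any fixed absolute tolerance
  yet still matter in log space.

* **Sampler path** (`loglik_vector`): a fixed-order Gauss-Legendre panel
  rule (7 nodes per panel) over breakpoints graded around *both* features
  of the integrand — the unit-scale Gaussian (or logistic transition,
  graded in units of 1/|f|) and the Cauchy spike (geometric grading, ratio
  3, extended adaptively so the narrowest spike in the batch is resolved
  out to the domain edge).  Grading by distance-to-singularity keeps the
  per-panel integrand analytic, so the composite rule converges
  geometrically.  The kernels are numba-compiled and evaluate all
  observations per posterior density call.  Tests pin this path to the
  reference path at 2e-7 (continuous) and 2e-4 (binary, worst corner at
  gamma ~ 1e-4 where the term is tail-dominated) over adversarial scale
  sweeps, and to the closed-form Gaussian-Cauchy convolution (Voigt
  profile — used only as an independent oracle) at ~1e-8 on realistic
  scales.

Numerical edge cases: `gamma <= 0` or `sigma <= 0` return log-posterior
-inf (so a sampler rejects) rather than raising; `f = 0` is an error for
continuous data (the model divides by f) and gives the exact coin-flip
log(1/2) for binary; an integral that underflows to zero maps to -inf.

## Posterior sampling

Random-walk Metropolis-Hastings on `(delta, log gamma[, log sigma])` with
independent Gaussian proposals and the log-transform Jacobian added to the
target.  Proposal scales default to (0.1, 0.25, 0.25) and adapt
multiplicatively during burn-in only (window of 50, scales multiplied by
`exp(acceptance - 0.3)` when acceptance leaves [0.15, 0.5]), then freeze,
so the retained chain is a valid time-homogeneous MH chain.  The chain
starts from robust statistics of the observed ratios `y_i/f_i` — median,
median absolute deviation (consistent location/scale estimates for Cauchy
samples), and the residual sd — because heavy-tailed posteriors punish
cold starts; binary chains start from the similarity-neutral (1, 0.5).
Defaults are 10,000 iterations with 2,000 burn-in; the study runs use
3,000/1,000 (the posterior is only 2-3 dimensional and mixes quickly under
adaptation; a correctness test compares a long thinned chain against
direct numerical normalization of the exact posterior on a grid).

## Prediction

Continuous: `npost` posterior draws x `nbeta` Cauchy random effects x `ny`
Gaussian labels per new point (defaults 1000 x 10 x 10); prediction sets
are equal-tailed empirical-quantile intervals, and the point prediction is
the predictive *median* (the Cauchy-mixture predictive has no finite mean;
a posterior-mean-delta plug-in is available via
`run_study(point_method="plugin")`).  Binary: the Bernoulli layer is
marginalized analytically — the predictive success probability `p_tilde`
is the mean of `expit(beta f)` over posterior and random-effect draws —
which leaves the estimate unbiased while removing its Monte-Carlo
variance; a label-sampling path is retained for fidelity testing.  The
label set at level 1-alpha keeps the favored label alone only when its
predictive mass reaches 1-alpha, otherwise both labels.  The batched
samplers used by the study runner share posterior and random-effect draws
across the test points of one replicate (fresh Gaussian noise per point);
each point's marginal predictive law is unaffected, only across-point
correlations within one replicate are introduced, which leaves
replicate-averaged metrics unbiased.

## Synthetic study design

`simulate` generates the two populations: `theta_S` has p/2 components
uniform on [-5, -0.75] and p/2 on [0.75, 5] (p = 50 including an intercept
column of ones; the other 49 features are standard Gaussian), and
`theta_T = theta_S + eps`, `eps ~ N(0, sigma_TL^2 I)` with
`sigma_TL^2 in {0, 0.25, 1, 4}`.  Source samples have n_S = 1000; target
training samples n_T in {20, ..., 250}; test sets 250 points.  Continuous
responses use Gaussian noise with sd 0.5 in both populations.  That value
is the one generator constant not pinned by the design description, and it
is calibrated against the design's own reference behavior: a target-only
least-squares fit at n_T = 250 should attain out-of-sample RMSE ~0.57
(= 0.5 * sqrt(1 + p/n_T)), and the transferred model's RMSE floor of
~0.52 equals sqrt(0.5^2 + (0.5 sqrt(p/n_S))^2), the noise floor plus the
source-estimation mismatch.  Both reproduce in this package's runs (the
baseline lands at 0.570).

Replicates are seeded by spawning independent child streams from one
master `SeedSequence`, so studies are exactly replayable and would
parallelize deterministically.  A replicate whose source fit fails (e.g. a
perfectly separated logistic sample) is skipped with a logged warning and
recorded in the output table's `attrs["skipped"]`; separation is detected
exactly (every observation on its own side of the fitted hyperplane), and
an opt-in ridge fallback (L2 strength 1e-6) keeps the fit finite when
requested.  The binary study runs opt into that fallback: under this
design the linear predictor has sd ~22, labels are near-deterministic, and
a source sample of 1000 points in 50 dimensions is perfectly separable in
a substantial, seed-dependent fraction of replicates — the unpenalized
logistic MLE does not exist there, while the negligible 1e-6 penalty
changes nothing else about the fit.  The downstream calibration absorbs
the (sometimes large) scale inflation of near-separated logistic estimates
through `delta`; that is the point of recalibrating.  Features are *not* re-standardized inside the study runner:
the generated features are standard Gaussian by construction, and the
intercept column would make column standardization degenerate.
`standardize_features` exists for real tabular workflows and applies
recorded training statistics to held-out data.

What the generator does *not* emulate: correlated or heavy-tailed
features, covariate shift between source and target feature distributions
(only the coefficients shift), non-linear structural components, and
label noise misspecification.  Passing tests therefore certify the
calibration machinery under the stated design, not robustness to those
departures; the generator accepts a user-supplied `generator` callback for
such scenarios.

## What the study runs show — and one honest discrepancy

At desk scale (30 replicates) the continuous results reproduce the
reference behavior within twice the replication standard errors: 95%
interval coverage ~96-98 across (n_T, sigma_TL^2) cells, RMSE ~0.51-0.53
at sigma_TL^2 = 0 regardless of n_T, rising to ~14 at sigma_TL^2 = 4
(the residual dissimilarity sqrt(p * sigma_TL^2) ~ 14 dominates).  Binary
AUC lands at ~98 (x100).

Binary *label-set coverage* under this design is structurally pinned near
100, not at the nominal 95: the simulated linear predictor has sd ~22, so
labels are near-deterministic (about 11% of test points have a true
success probability inside (0.05, 0.95)).  Any approximately calibrated
predictive probability then produces single-label sets that are correct
with probability ~0.998 and two-label sets otherwise — both covered —
and under strong divergence (sigma_TL^2 = 4) the fitted Cauchy scale makes
`arctan(delta/gamma)/pi + 1/2 < 0.95`, so *every* set contains both labels
and coverage is exactly 100.  The package reports the honest number; the
acceptance suite keeps the nominal-95 comparison as a known red check
rather than adjusting the generator or the set rule to chase it.

## Numerical and design choices, briefly

* Negative round-off under the similarity-law square root is clamped to 0
  (identical vectors must give exactly gamma = 0); a gamma produced on an
  unconstrained scale is handled structurally by sampling log gamma.
* Quantile intervals are equal-tailed; highest-density regions from
  samples are out of scope.
* AUC is Mann-Whitney (ties 1/2), computed on the predictive success
  probability as the ranking score.
* Coverage tables are reported x100 only at the reporting layer; the
  programmatic API stays on the probability scale.
* Chains, replicate counts and predictive sizes used by
  `scripts/acceptance.py` (30 replicates; 3,000-iteration chains;
  npost, nbeta, ny = 500, 10, 4) are the package's desk-scale defaults for
  the study; all are parameters.

## Known limitations

* The similarity law is exact only for centered Gaussian features and
  linear structural components; elsewhere it is a first-order / CLT
  approximation (the framework still applies, as the binary study — where
  the law is approximate — shows).
* The model explains source-target dissimilarity through a scale-free
  random effect multiplying f(x); purely additive shifts are absorbed
  only via the intercept component of f.
* Multi-class outcomes and differing source/target feature spaces are out
  of scope.
* The marginal-likelihood integrals assume sigma is homoscedastic across
  target observations.
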