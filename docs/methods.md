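# Methods

## Model

For study *i* and disease group *j* (1 = disease-free, 2 = diseased), the
observed data are the group size N_ij and the counts x_ijt of patients
with test result above each reported threshold C_it, t = 1..T_i, with
C_i1 < ... < C_iT. The x_ijt are non-increasing in t by construction of
the data; the model reproduces this automatically.

**Within study.** The multinomial spread of one group's results across
the T_i + 1 threshold intervals is written as a chain of conditional
binomials:

    x_ij1 ~ Binomial(N_ij, pr_ij1)
    x_ijt | x_ij,t-1 ~ Binomial(x_ij,t-1, pr_ijt / pr_ij,t-1)

This factorisation is exact (the test-suite verifies equality with the
direct multinomial log-pmf to 1e-9 including all combinatorial
constants), handles studies with a single threshold as the base case, and
keeps every binomial probability parameter free in (0,1) — no ordering
constraints are ever imposed during sampling.

Test results are assumed logistic on a transformed scale: with
g(C) = (C^λ − 1)/λ for λ ≠ 0 and log C for λ = 0,

    logit pr_ijt = (mu_ij − g(C_it)) / sigma_ij .

λ = 1 corresponds to symmetric logistic test results, λ = 0 to
log-logistic; decreasing λ means increasing right skew. λ can be fixed or
estimated (default prior Uniform(−3, 3); Uniform(1, 10) available for
sensitivity analysis). Thresholds must be strictly positive; zero or
negative thresholds are rejected rather than silently shifted, because no
principled shift constant exists — any rescaling is the analyst's
preprocessing decision.

**Between studies.** (mu_i1, mu_i2, log sigma_i1, log sigma_i2) is
quadrivariate normal with means (m_mu1, m_mu2, m_sigma1, m_sigma2),
SDs (tau_mu1, tau_mu2, tau_sigma1, tau_sigma2) and one of three
correlation structures:

* **full** — six free correlations, constrained only by positive
  definiteness (enforced by rejection at every evaluation, never by
  silent repair);
* **structured** — two free correlations: rho_mu between the two
  locations and a common rho_mu_sigma between each location and its own
  log-scale. All cross-correlations are induced (e.g.
  corr(mu_i1, log sigma_i2) = rho_mu * rho_mu_sigma), never free. Draws
  use the exact conditional decomposition
  (mu_i1; mu_i2 | mu_i1; log sigma_ij | mu_ij);
* **independence** — all correlations zero.

Study-level covariates (mean-centered by default) shift any subset of the
four means, `mu_ij -> m + alpha_r' z_ir`; the default configuration in the
examples regresses the two locations only.

**Priors.** Normal(0, 10²) on all means and meta-regression coefficients,
Uniform(0, 5) on between-study SDs, Uniform(−1, 1) on correlations,
Uniform(−3, 3) on λ when estimated. These are deliberately weakly
informative on the transformed-threshold scale; see "prior support"
below for the one practical consequence that matters.

## Sampler

No gradient-based probabilistic-programming backend is assumed; the
sampler is a Metropolis-within-Gibbs scheme written directly against the
model structure, operating on a flattened row representation so one
likelihood evaluation is a handful of vectorised array operations:

* study effects: coordinate-wise random-walk Metropolis proposed for all
  studies simultaneously, with per-study proposal scales adapted during
  warmup (target acceptance 0.44, Robbins-Monro decay t^-0.6);
* population means and coefficients: exact conjugate multivariate-normal
  Gibbs draw;
* heterogeneity SDs tau: univariate slice sampling in the centered
  parameterisation, interleaved with a non-centered slice step that holds
  the standardised study residuals fixed (an ancillarity-sufficiency
  interweaving). The pair mixes well both under strong heterogeneity and
  when tau is near zero, where a purely centered scheme stalls;
* correlations: univariate slice sampling with −inf log-density at
  non-positive-definite proposals;
* λ: univariate slice sampling plus a joint Metropolis move that
  transports all location/scale-type parameters through the affine map
  aligning the transformed threshold ladder between the current and
  proposed λ (matching the mean and SD of g(λ) over the distinct observed
  thresholds). The map is an exactly invertible deterministic
  diffeomorphism, with Jacobian a^(2S + 4 + #mu-coefficients) in the
  acceptance ratio (a = frame-scale ratio, S = number of studies). This
  move travels along the strong posterior ridge coupling λ to the
  locations, which otherwise makes λ the slowest-mixing parameter in the
  model; three attempts are made per iteration, with the proposal SD
  adapted toward 30% acceptance during warmup.

A `fixed_effects` mode (all tau = 0, effects pinned to the population
means, means updated by slice sampling against the likelihood directly)
supports single-study and common-effect analyses.

Defaults are 4 chains of 1000 warmup + 1000 kept iterations; a seed is
mandatory, and all chains derive their generators from it via
`SeedSequence.spawn`, so runs are exactly reproducible. Convergence is
summarised per parameter with rank-normalised R-hat and bulk/tail ESS
(arviz); R-hat > 1.05 flags, but does not abort, a fit. When λ is
estimated it is listed first in the report because it is the parameter
most prone to high autocorrelation.

**Initialisation.** Per study-group, a least-squares fit of the empirical
logits against g(C) gives starting (mu, sigma) (falling back to a crude
location match when a group has fewer than two thresholds or a flat
slope); hyperparameter starts are the moments of those estimates, and
chains are jittered for overdispersion.

## DIC

The residual deviance is computed on the conditional binomial terms of
the factorisation — the same sampling statement the likelihood codes —
as 2 Σ [x log(x/(n p)) + (n−x) log((n−x)/(n−n p))] with the usual zero
conventions. Dbar is the posterior mean deviance; the plug-in deviance is
evaluated at the posterior means of the conditional binomial
probabilities (the direct parents of the likelihood); pD = Dbar − Dplug;
DIC = Dbar + pD. pD < 0, a known DIC pathology, attaches a warning rather
than failing.

## Summaries

Summary accuracy at threshold C evaluates the link at the random-effect
means per posterior draw:

    logit fpr(C) = (m_mu1 − g(C)) / exp(m_sigma1)
    logit tpr(C) = (m_mu2 − g(C)) / exp(m_sigma2)

using that draw's λ when estimated. The headline point estimate is the
posterior median of the curve (transformation-equivariant); the curve at
the posterior-mean hyperparameters is also attached since the two
conventions are both in circulation. Credible bands are central 95%
quantiles across draws. Prediction bands redraw, for each posterior draw,
one new study's effects from that draw's between-study law under the
fitted correlation structure; they are pointwise, not simultaneous.
The default grid is 200 log-spaced points over the observed threshold
range; grids beyond the data are allowed but flagged as extrapolation,
since estimates at extreme thresholds rest entirely on the parametric
tails. The SROC curve is the parametric (fpr(C), tpr(C)) locus.

Threshold selection maximises the weighted Youden index
J_w = 2(w·tpr + (1−w)(1−fpr)) − 1 over the grid (w = 0.5 is the classical
J = tpr − fpr; ties resolve to the smallest threshold). Covariate effects
on a location are reported as ratios exp(delta · alpha) of mean test
results per covariate change delta; this interpretation is valid only on
the log scale, so any transform other than fixed λ = 0 raises instead of
returning a number that would be misread.

## Synthetic data generator

`ScenarioSpec`/`generate` simulate from the model's own generative
process: study effects from the between-study law, thresholds as random
subsets of a common log-spaced ladder (mirroring how real studies report
different cutoff sets), counts through the conditional binomial chain,
optional uniform dropping of thresholds (never all) for missingness, and
optional study-level covariates acting on the centered scale. The default
scenario — 20 studies of 50–500 patients per group, 1–7 thresholds each
over 50–1500 units, log-logistic results with disease-free/diseased
geometric means ≈ 100 vs ≈ 490 units, logistic scale 1, tau_mu = 0.5 and
tau_sigma = 0.25 — is sized and shaped like a typical right-skewed
biomarker meta-analysis with moderate heterogeneity.

A second path, `generate_individual_level`, draws individual results
from the transformed logistic law, inverts the Box-Cox transform (with a
resampling guard at the transform's domain boundary for λ ≠ 0) and counts
exceedances; the two paths agree in distribution, which the test-suite
checks, validating the link independently of the count-level code.

What the generator does *not* emulate: selective reporting of data-driven
"optimal" thresholds (a recognised bias in real meta-analyses), digitised
ROC-plot extraction error, assay mixtures, or imperfect reference
standards. Passing recovery tests therefore show correctness of the
fitting machinery under the model's own assumptions, not robustness to
these real-data pathologies.

## Benchmark simulation sizes

The test-suite's recovery benchmarks use 10 replicates of 30 studies ×
500 patients per group × 5 thresholds for hyperparameter and curve
recovery (independence structure, λ = 0 fixed; 2 chains × 400 + 600
iterations), and 5 replicates per λ ∈ {0, 0.5} of 40 studies × 1000
patients for transform recovery (2 chains × 500 + 700). These sizes give
stable pass/fail behaviour at fixed seeds while keeping the whole suite
in a few minutes on one CPU.

**Prior support and scenario design.** When specifying a generating
scenario at λ ≠ 0, heterogeneity SDs must be read on the transformed
scale: carrying a λ = 0 scenario onto the λ = 0.5 scale stretches the
location axis by roughly the ratio of transformed-ladder SDs (~18× for
the default 50–1500 range), which would push tau_mu far outside the
Uniform(0, 5) prior — a truth the model cannot recover *by design*, since
the posterior then prefers compressing the scale through a smaller λ. The
λ = 0.5 benchmark therefore sets tau_mu = 2 on that scale (moderate
heterogeneity, within prior support), with means and scales carried over
by the affine ladder alignment (`synthetic.rescale_hyperparams`).

## Numerical choices

* Probabilities are clipped to [1e-12, 1 − 1e-12] before logs, guarding
  against underflow at extreme thresholds.
* The Box-Cox power branch uses (C^λ−1)/λ for |λ| ≥ 1e-4 (exact at λ = 1),
  expm1(λ log C)/λ for 1e-8 ≤ |λ| < 1e-4, and log C below — continuous
  across the λ = 0 boundary to well under 1e-5.
* tau is slice-sampled on (1e-6, 5); the floor avoids a numerically
  singular between-study covariance and is far below any practically
  distinguishable heterogeneity.
* Duplicated thresholds within a study-group are an error, not merged:
  two different counts at one threshold have no unambiguous resolution.
* `from_accuracy` rounds reported sensitivities/specificities to counts
  and errors if rounding breaks monotonicity, rather than guessing which
  count to repair.
* Log-likelihoods include all binomial/multinomial constants, so oracle
  comparisons are exact rather than up-to-a-constant.

## Limitations

* One λ for both groups and all studies; group-specific or study-random
  transforms are out of scope.
* No two-parameter (shifted) Box-Cox, so the test scale must be positive.
* DIC is the only model-comparison criterion provided.
* Prediction intervals are pointwise.
* The sampler is exact but not gradient-based; for very large
  meta-analyses (hundreds of studies) per-iteration cost grows linearly
  and a longer run may be needed for the full correlation structure.
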