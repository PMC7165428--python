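# Methods

## The problem

Biomonitoring surveys of diverse communities — here, wetland
macroinvertebrates identified morphologically or by bulk-sample DNA
metabarcoding — never detect everything that is present. False absences
bias richness downward, distort compositional dissimilarity, and sap the
power of any test for ecosystem change. `commocc` implements the
hierarchical modelling chain that corrects for imperfect detection and then
asks, by simulation, how much change a given monitoring design could
actually see.

## Multispecies occupancy model

For taxon k, site visit i, replicate sample j:

    w_k   ~ Bernoulli(Omega)                      membership in the regional pool
    z_ik  ~ Bernoulli(w_k psi_ik)                 occupancy state
    y_ijk | z_ik ~ Bernoulli(z_ik p_ijk)          detection
    logit(psi_ik) = lpsi_k + betalpsi_k . x_i
    logit(p_ijk)  = lp_k   + betalp_k  . v_ij

Taxon intercepts and slopes are exchangeable normal random effects:
lpsi_k ~ N(mu_lpsi, sigma_lpsi^2) and so on. The observed taxon list is
augmented with all-zero pseudo-taxa up to a superpopulation of M; the
posterior of gamma = sum_k w_k estimates regional richness including taxa
the survey never saw. Covariate selection uses Kuo–Mallick indicators
V_x ~ Bernoulli(0.5) multiplying each covariate's contribution; the
posterior frequency of V_x = 1 is its inclusion probability. One indicator
is shared across taxa per covariate (the covariate enters every taxon's
linear predictor or none) while slopes stay taxon-specific.

Priors (configurable in `PriorSpec`): hyper-means Normal(0, 1.5^2) on the
logit scale, hyper-SDs Uniform(0, 5), Omega ~ Beta(1, 1). These are the
weakly informative defaults standard for logit-scale community occupancy
models; 1.5 keeps the implied probability scale near-uniform, and 5 is far
above any plausible logit-scale spread.

### Sampler

Inference is adaptive random-walk Metropolis-within-Gibbs, vectorised
across taxa:

- z and (w, z) have exact full conditionals. For never-detected taxa, w is
  updated with z marginalised out — P(w=1 | all y=0) mixes Omega against
  the probability of total nondetection — and z is then drawn given w.
  This block update avoids the sticky w|z conditional.
- Omega and the hyper-means are conjugate. Hyper-SDs use random-walk
  Metropolis on log sigma with the uniform-prior bound enforced.
- Taxon intercepts and slopes use per-taxon random-walk proposals whose
  log step sizes adapt by Robbins–Monro toward an acceptance rate of 0.35
  during burn-in only; adaptation is frozen afterwards so the chain is a
  valid time-homogeneous kernel in the sampling phase.
- When a taxon has w = 0, or a covariate has V_x = 0, the parameters the
  likelihood no longer touches are refreshed directly from their community
  prior — required for the augmentation and indicator moves to mix.
- With no covariates the Bernoulli likelihoods collapse onto sufficient
  statistics (occupied-visit counts; detections and trials among occupied
  cells), which is the hot path for the recovery studies.

The implementation was cross-validated against JAGS (rjags) on a
50-taxon, 60-visit dataset: posterior means and 95% intervals of all four
community hyperparameters agree to within Monte Carlo error.

Default run lengths are 3 chains x 20,000 iterations, 10,000 burn-in,
thin 10, all configurable. Convergence is advisory: `diagnostics()`
reports R-hat per scalar trace (flagging >= 1.1), acceptance rates and
inclusion probabilities, and never discards chains silently.

### Diagnostics

`gelman_rubin` implements the classic between/within-chain potential scale
reduction sqrt(((n-1)/n W + B/n)/W); a `split=True` variant splits chains
in half first. When every chain is constant the statistic is undefined and
reported as NaN rather than 1. `dunn_smyth_residuals` gives randomized
quantile residuals for the Bernoulli observation model — exactly standard
normal under the true model — with a deterministic midpoint mode for exact
tests. Fitted probabilities exactly 0 or 1 that contradict the observation
produce infinite residuals, left for the caller to flag.

## N-mixture variant

For count data the occupancy state is replaced by latent abundance:
N_ik ~ Poisson(w_k lambda_ik) with log(lambda_ik) = llam_k + slopes, and
y_ijk | N_ik ~ Binomial(N_ik, p_ijk). Across taxa, llam_k is a normal
random effect on the log scale (log-normal lambda heterogeneity).

Latent N updates use a discrete random walk (+-1, +-2) with three interior
steps per sweep; visits with a single replicate instead use the exact
closed form N = y + Poisson(lambda(1-p)). The standalone `update_N` /
`full_conditional_N` compute the exact truncated-enumeration conditional
(tail mass < 1e-10) and serve as the oracle the sampler is tested against.
For never-detected augmented taxa the total-nondetection likelihood has
the closed form exp(sum_i lambda_ik (s_i - 1)) with s_i the product of
(1-p_ij) over replicates, so w mixes without instantiating N.

Poisson overdispersion is deliberately not modelled. The expected-richness
check `expected_richness_under_count_model` — relative abundances
pi_k = lambda_k / sum lambda, expected observed richness
sum_k [1-(1-pi_k)^n] for n individuals counted — is the diagnostic for
that misspecification: aggregated (clumped) individuals make the model
predict more taxa per fixed count than a survey actually records.

## Diversity

Observed matrices collapse replicates by any-detection; corrected
matrices are the posterior latent z draws, so corrected alpha >= observed
alpha per site and gamma >= observed richness by construction. Beta
diversity is pairwise Jaccard (default) or Sorensen dissimilarity on
presence-absence, ignoring shared absences; an empty site is defined
maximally dissimilar (1) to non-empty sites and flagged. Aggregation to
family rank is logical OR over member genera (sums for counts), which can
only create shared presences — hence genus-level dissimilarity >=
family-level, the direction of the resolution contrast
`resolution_dissimilarity_contrast` reports as a percent of the
family-level mean. `percent_increase` rounds half away from zero to whole
percent, matching how such gains are reported.

## Metacommunity simulation and power

The power engine emulates monitoring of a quasi-neutral metacommunity:

1. **Baseline**: a site x taxon matrix with cells Bernoulli(psi_k), psi_k
   from fitted draws or a parametric logit-normal.
2. **Turnover**: every simulated year, the reference year included, is an
   independent curveball permutation of the baseline — trades between row
   pairs that preserve all row and column sums exactly, the fixed-margin
   null of random assembly. Because each curveball trade reallocates every
   exchangeable column between a row pair, on the order of 5 x n_rows
   trades reach the uniform distribution on the margin class; the default
   uses 10 x n_sites. Permuting the reference year too is essential: it
   makes reference and unimpacted years exchangeable, so the composition
   test is calibrated at severity zero. `calibrate_turnover` searches the
   trade count whose mean year-to-year within-site Jaccard matches a
   target.
3. **Stressor**: a fraction `severity` of all occurrences is removed —
   exactly round(severity x total), so the x-axis "reduction in community
   occupancy" is exact — with removal probability proportional to
   (1 - tolerance_k). Tolerances come from a Gaussian copula with Spearman
   correlation rho to occupancy (rho = +-1 reproduces/reverses ranks
   exactly; rho = 0 decouples them).
4. **Observation**: detection is Bernoulli(presence x p_k) per replicate,
   with p_k drawn from logit-normal presets per sampling approach. The
   preset means order morphology-based family data below DNA family and
   DNA genus data, reflecting the fitted detectability ordering of those
   approaches; exact preset values are configuration, not estimates.
5. **Test**: an mvabund-style sum of per-taxon binomial likelihood-ratio
   statistics between reference and impacted samples (replicates collapsed
   to site-level detection), with p-values from permuting site labels
   (499 resamples by default; p = (1 + #{perm >= obs})/(1 + R)). Taxa
   invariant across all sites are dropped (their LR is identically zero).
6. **Power**: a design succeeds in one simulation if it rejects at alpha
   in at least one of two post-impact years ("within 2 years"); requiring
   both years is available via `require_both_years`. Power is the success
   fraction over `n_sim` simulations, and the minimum detectable severity
   is the smallest severity with power > 0.5, linearly interpolated
   between grid points.

A consequence of margin-preserving turnover is that the permutation null
is wide relative to the detection-noise-only variation between coupled
years, so moderate severities are genuinely hard to detect — the model's
version of "near-random assembly swamps local signals". Power is
recovered by aggregating across sites, exactly the design message the
power curves carry.

## Synthetic data

The generator produces the survey structure the models assume: a
multi-year design (default preset: 12 sites x 6 years = 72 site visits, 2
replicate samples per visit), 360 genera nested in 130 families (1-8
genera per family, uniformly assigned), occupancy/detection parameters
drawn from the logit-normal community distributions, three standardized
occupancy covariates (emulating flood frequency, days since ice melt, max
water temperature), one continuous detection covariate (sequencing depth)
and a categorical primer-pair indicator expanded to treatment contrasts.
Community hyperparameter defaults (mean occupancy ~0.25 with wide spread,
mean per-replicate detectability ~0.6, near-neutral covariate effects)
were chosen once to produce a diverse, imperfectly detected assemblage of
the kind such wetland surveys record. Missing replicates are masked, not
zero-filled.

What the generator does not emulate: sequence-level error (reads,
chimeras, primer mismatch), spatial structure or dispersal, taxonomic
misassignment, and abundance aggregation beyond Poisson. Passing tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions, not robustness to the full error structure of
real metabarcoding data.

## Problem sizes in the test suite

Recovery studies run at 50 taxa x 60 site visits x 3 replicates (40
replicate fits for hyperparameter coverage; intervals must cover in 85%)
and gamma_true = 120 with M = 240 (20 replicate fits); chains are 2 x
6,000-16,000 iterations with 2,000-4,000 burn-in, lengths at which the
interval endpoints are stable. The small-instance oracle check compares
50,000 MCMC draws against a 601^2-point quadrature grid. The type-I study
uses 1,000 null communities; power curves use 100 simulations per design x
severity point on a 2-sites x 2-replicates x 2-presets grid. These sizes
are the package's chosen compromise between Monte Carlo noise and a test
suite that runs in minutes.

## Known limitations

- Indicator (V_x) chains inherit the slow mixing documented for
  Kuo–Mallick selection in highly parameterised MSOMs; per-indicator
  traces are exposed so users can judge mixing themselves.
- Frequentist coverage of the 95% interval for community hyper-means at
  desk scale is slightly below nominal (~93% for the occupancy hyper-mean
  at 60 visits) — a property of the exact posterior (reproduced by JAGS),
  driven by the psi/p trade-off in logit-scale occupancy models, not of
  the sampler.
- The N-mixture model assumes Poisson dispersion; overdispersed counts
  surface through the expected-richness check rather than a fitted
  dispersion parameter.
- No spatial random effects, autologistic terms, or dispersal dynamics.
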