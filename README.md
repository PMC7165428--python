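# commocc

Hierarchical multispecies occupancy modelling for community biomonitoring:
how many taxa does a survey miss, how does imperfect detection distort
diversity, and how much ecosystem change could a monitoring design
actually detect?

`commocc` is aimed at ecologists analysing replicated presence–absence or
count surveys of diverse assemblages — the motivating case is wetland
macroinvertebrate monitoring, where bulk samples are identified either
morphologically or by DNA metabarcoding, and where false absences are the
rule rather than the exception.

## The models

For taxon *k*, site visit *i*, replicate sample *j*:

```
w_k   ~ Bernoulli(Ω)                    membership in the regional pool
z_ik  ~ Bernoulli(w_k ψ_ik)             occupancy state
y_ijk | z_ik ~ Bernoulli(z_ik p_ijk)    detection
logit(ψ_ik) = lpsi_k + betalpsi_k · x_i
logit(p_ijk) = lp_k  + betalp_k  · v_ij
```

Taxon intercepts and slopes are normal random effects governed by
community hyperparameters (μ, σ). Augmenting the observed taxon list with
all-zero pseudo-taxa up to a superpopulation *M* makes regional richness
γ = Σ w_k an estimand: the posterior counts the taxa never seen.
Kuo–Mallick indicators V_x ~ Bernoulli(0.5) give posterior inclusion
probabilities for occupancy and detection covariates. A community
N-mixture variant (`N_ik ~ Poisson(w_k λ_ik)`, `y | N ~ Binomial(N, p)`)
handles replicated counts. Inference is adaptive Metropolis-within-Gibbs,
vectorised across taxa, with Gelman–Rubin diagnostics and Dunn–Smyth
(randomized quantile) residuals.

Around the models sit detection-corrected diversity (α from latent
states, β as Jaccard/Sørensen dissimilarity, γ from augmentation, genus→
family aggregation) and a power engine: baseline metacommunities from
fitted occupancy, year-to-year turnover by fixed-margin (curveball)
permutation, tolerance-weighted stressors removing an exact fraction of
occurrences, imperfect observation, and an mvabund-style
sum-of-likelihood-ratios permutation test — swept over designs to find
the minimum detectable reduction in community occupancy.

## Worked example

`examples/fit_occupancy.py` simulates a 30-taxon community surveyed at 60
site visits with 3 replicate samples, discards the taxa the survey never
detected, and refits with data augmentation (M = 60):

```
true gamma 30, observed 29
mu_lpsi      true -1.50  posterior -1.39 [-1.81, -0.99]
sigma_lpsi   true  1.20  posterior  0.83 [ 0.47,  1.34]
mu_lp        true -0.50  posterior -0.59 [-1.02, -0.21]
sigma_lp     true  1.00  posterior  0.84 [ 0.51,  1.28]
gamma        true    30  posterior  29.9 [29, 33]
parameters with R-hat >= 1.1: none
```

Each line compares a generating community hyperparameter (the mean and
spread of taxon-level occupancy and detectability on the logit scale)
with its posterior mean and 95% interval; all four intervals cover the
truth. The γ line is the augmentation estimate of regional richness: the
survey observed 29 taxa, and the posterior [29, 33] correctly brackets
the 30 that actually existed. The other scripts in `examples/` walk
through survey simulation, the N-mixture count model and its
expected-richness misspecification check, detection-corrected diversity
with the genus-vs-family dissimilarity contrast, and the power sweep.

A thin CLI mirrors the pipeline (`commocc simulate | fit | diversity |
power`), each subcommand taking `--config`, `--seed` and `--out` and
writing a reproducibility manifest beside its outputs.

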