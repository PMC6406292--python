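# Methods

## The two-stage model

The package estimates how area-level walkability relates to the prevalence
and geography of overweight and obesity, using a two-stage design that
separates individual-level composition from area-level context.

**Stage 1 — indirect standardisation.** Each dichotomous outcome (overweight
vs. normal/underweight, obese vs. normal/underweight) is modelled at the
individual level by logistic regression

    l_ij = alpha + x_i' beta,        Y_ij = expit(l_ij),

once with no covariates (the null model, whose fitted probability is the
pooled prevalence exactly) and once with the full categorical covariate
roster (sex, 5-year age group, language, education, relationship, employment,
insurance, smoking, psychosocial distress, diagnosed and treated chronic
conditions, functional limitation).  Predicted probabilities are summed
within areas to give *unadjusted* and *adjusted* expected counts e_j.  With
an intercept in the model, the score equation forces Σ_j e_j = Σ_j o_j for
both offset kinds; this identity is asserted to 1e-6 relative tolerance.

**Reference-exclusion denominators.** The prevalence of one elevated BMI
category is always computed against the normal/underweight reference with the
other elevated category removed from the denominator (e.g. male overweight =
20,802/(44,690 − 8,912) = 58.1%).  This is the only convention under which
every percentage in the bundled cohort-margins table is reproducible from its
printed counts, so tabulation and stage-1 fits both use it.

**Stage 2 — BYM spatial Poisson regression.** Per area,

    o_j ~ Poisson(theta_j e_j),
    log(theta_j) = alpha + x_j' beta + s_j + u_j,

where x_j holds walkability quartile and/or disadvantage quintile dummies
(reference = first level; the interaction model crosses the non-reference
dummies, 12 terms), u_j ~ N(0, sigma_u^2) i.i.d., and s follows the intrinsic
CAR prior: s_j | s_{-j} ~ N(mean of neighbours, sigma_s^2 / k_j) on the
binary contiguity graph.  exp(alpha) is the study-area prevalence ratio and
exp(beta) are prevalence ratios against the reference level.  The six-model
suite is: (1) null/unadjusted offsets, (2) null/adjusted, (3) +walkability,
(4) +disadvantage, (5) +both, (6) +both+interaction; models are compared by
DIC on identical data.

## Sampler

Metropolis-within-Gibbs:

* **s** — single-site random-walk Metropolis, vectorised over colour classes
  of the contiguity graph (a greedy colouring; areas in an independent set
  have conditionally independent updates).  After each sweep s is re-centred
  to per-component mean zero and the subtracted size-weighted mean is added
  to alpha.  The ICAR density is flat along that direction, and on a
  connected graph the shift leaves every theta_j unchanged; with several
  components the single scalar intercept cannot absorb distinct component
  means exactly, which is one reason the exclusion filter removes
  neighbourless areas before fitting (all shipped scenarios are connected).
* **u, alpha, beta** — random-walk Metropolis (u vectorised across areas;
  each fixed effect updated against the subset of areas its 0/1 dummy
  touches).
* **tau_s = 1/sigma_s^2, tau_u = 1/sigma_u^2** — exact gamma Gibbs draws:
  tau_s ~ Gamma(a + (n−C)/2, b + ½Σ_{i~j}(s_i−s_j)^2) with C connected
  components; tau_u ~ Gamma(a + n/2, b + ½Σu_j^2).

Proposal scales adapt in batches of 50 during burn-in only (multiplicative
steps of size min(0.25, batch^-1/2), targeting ~0.44 acceptance), so detailed
balance holds for every retained draw.  Chains are initialised at
alpha = log(Σo/Σe), small random s (component-centred) and u, and moderate
precisions; fixing a precision also pins the corresponding field at zero with
a matched proposal scale.

**Priors.** N(0, 1000) on alpha and each beta (effectively flat at this data
scale) and Gamma(0.5, 0.0005) on both precisions — the long-standing
disease-mapping convention of the WinBUGS literature.  Be aware that this
hyperprior is *informative at desk scale*: it places roughly 0.2% prior mass
on sigma_s^2 > 0.09, so with small expected counts (e_j ≲ 10) the posterior
for the variance components is prior-dominated.  Both priors are
configurable on `BYMSpec`.

**Protocol.** The headline preset mirrors the source analysis: 2 chains,
5,000 kept draws each, thinning 250.  The test preset (2 × 500 kept × thin
10) is used throughout the test suite and the acceptance script so that a
full model fit takes seconds; burn-in defaults to one ninth of the sampling
phase (10% of total iterations).  Convergence is monitored with the
potential scale reduction factor (R-hat) on alpha, the betas and both
variances; values above 1.1 are recorded as warnings in the output, never
raised.  sigma_u^2 is weakly identified when true unstructured variation is
far below Poisson noise, and occasional R-hat warnings on it at test-preset
lengths are expected and benign.

**Summaries.** Posterior medians and 2.5/97.5 percentiles of pooled draws.
DIC uses the "focused" effective-parameter count: pD = mean(D) − D(posterior
mean of the per-area linear predictor), which is stable in the presence of
random effects; the per-parameter alternative is not offered.  The spatial
fraction rho is computed per kept draw as Var_areas(s)/(Var_areas(s) +
Var_areas(u)) and summarised by its posterior median; a draw with zero total
variance contributes 0.5 by convention and is flagged.  Risk surfaces are
per-area posterior medians of exp(s+u), exp(s) and exp(u) (medians, to match
the summary convention; the Total surface is the median of per-draw products,
not the product of medians), classed into quintiles.

## Walkability index

Three components per area — residential dwelling density, 3+-way
intersection density, land-use-mix entropy −Σ p_k ln p_k / ln K — are each
scored into deciles 1..10 by average rank, summed to a 3..30 total, and cut
into empirical quartiles (low, low-medium, medium-high, high).  Tie rule
everywhere (deciles, quartiles, map quintiles): values get average ranks and
bin = ceil(B·rank/n), so a value exactly on a cut-point falls in the lower
bin; the rule is deterministic and invariant under strictly increasing
transforms.  Whether the source index cut quartiles empirically or at fixed
score ranges is not documented; empirical quartiles are implemented.

## Synthetic cohort generator

The source cohort is access-restricted, so all tests run on synthetic data
with the structure the analysis assumes:

* **Geography** — a 254-area graph (16×16 queen lattice minus two cells) by
  default; GAL files or GeoJSON polygons can supply real geographies.
* **Populations** — log-normal respondent counts calibrated to median 212
  and IQR 110–363 (the source study's per-area distribution), rounded with
  floor 1.
* **Covariates** — drawn independently per individual with marginal
  frequencies proportioned from the published cohort characteristics.  Only
  the margins are published, so joint covariate structure is not emulated —
  a known fidelity limit.
* **Outcome** — P(high BMI) = expit(baseline_logit + covariate effects +
  area log relative risk), split overweight/obese with probability
  `obese_split` (0.344 by default, the published high-BMI composition).
  This equals a three-class multinomial logit whose reference-exclusion
  conditionals are exactly logistic with intercepts shifted by ln(1−split)
  and ln(split), so both stage-1 analyses are correctly specified.  With
  `area_effect_scale="log_risk"` the area term instead multiplies the
  individual probability (capped at 0.995), making area effects exact
  prevalence ratios at any baseline — the logit placement is only equivalent
  for rare outcomes.
* **Area structure** — s from the ICAR distribution, realised spectrally
  (coordinates along Laplacian eigenvectors with eigenvalue λ > 0 drawn with
  variance sigma_s^2/λ; null-space coordinates zero, hence exact
  per-component sum-to-zero); u i.i.d. normal; walkability quartiles and
  disadvantage quintiles assigned by thresholding independent smooth ICAR
  draws at empirical quantiles (balanced class sizes, ties broken by area
  order), or uniformly at random with `spatial_covariates=False` for
  confounding-free experiments.

All randomness flows through one integer seed (split into independent
streams for populations, area effects, covariates and outcomes); identical
seeds give byte-identical CSVs.

## Validation experiments and their design

* **ICAR sampler oracle** — the empirical covariance of 50,000 draws on a
  4-node path is compared entrywise (3 MC standard errors) with
  sigma_s^2 L^+, the pseudo-inverse closed form on the sum-to-zero subspace.
* **Sampler-vs-integration oracle** — on a 3-area path with both precisions
  fixed, MCMC posterior means of alpha, every s_j and every u_j are compared
  (tolerance 0.02, ≈4 MC standard errors) with dense numerical integration:
  s parameterised in the Laplacian eigenbasis, u integrated out per area on
  a quadrature grid.
* **Parameter recovery** — 20 replicates of a known-truth scenario: 254
  areas, ~100 respondents each, walkability gradient (1, 0.97, 0.92, 0.85),
  sigma_s = 0.3, sigma_u = 0.05, fitted with the walkability model at the
  test preset.  Design choices that make this a test of the machinery rather
  than of asymptotics: area effects on the log-risk scale (the model's own
  scale); a rook lattice, whose larger ICAR marginal variance
  (mean diag L^+ ≈ 0.75 vs ≈ 0.30 for queen) keeps sigma_s^2
  likelihood-identified against the informative hyperprior at e_j ≈ 30;
  zero individual-covariate and disadvantage effects so the fitted model
  matches the generative structure; a small obese split so
  reference-exclusion barely perturbs denominators.  The intercept's target
  is the identifiable value implied by offset calibration,
  −log(Σ e_j exp(x_j'beta + s_j + u_j)/Σ e_j), computed per replicate from
  the truth table.
* **DIC model selection** — 20 replicates generated under the Model-5
  analogue with both covariate gradients active (down to 0.85) and
  *independently assigned* area covariates: spatially smooth covariates are
  collinear with the ICAR field, which otherwise absorbs their signal and
  flattens DIC differences.  Chains are moderately longer here (2 × 400 ×
  thin 5) because model choice rides on DIC differences of a few units,
  within MC noise of very short chains.

Problem sizes throughout (36–254 areas, tens of thousands of synthetic
individuals, 500–2,500 kept draws) were chosen so a full suite run completes
in minutes on one CPU while keeping every check likelihood-driven.

## Degenerate inputs and numerical choices

Implausible anthropometry (outside 30–250 kg, 1.0–2.5 m by default) codes to
missing and is logged; non-positive values are errors.  Perfect separation
is detected before fitting (outcome constant within a covariate level) and
reported naming the covariate.  Predicted probabilities are clamped to
(1e-12, 1−1e-12) so extreme log odds cannot round to 0 or 1.  Stage-1 IRLS
converges when the maximum absolute score is below 1e-8 (at most 100
iterations).  Areas with zero analysis-subset respondents or zero neighbours
are excluded (iterated to a fixed point, since removals can isolate further
areas) and logged; the ICAR conditional is undefined at k = 0, so fitting
refuses neighbourless areas outright.  GAL files with asymmetric neighbour
lists are rejected, not silently symmetrised.  The Gelman-Rubin statistic
reports 1.0 for identical chains and infinity for separated chains with zero
within-chain variance; the sample ACF of a constant series is flagged as
undefined (NaN).

## Known limitations

* Conditional likelihood subtleties of the source's "conditional
  fixed-effects" phrasing are not reproduced: ordinary ML logistic
  regression is used, because expected counts require absolute
  probabilities, which conditional likelihoods do not provide.
* The Poisson likelihood ignores the binomial upper bound of per-area
  counts; for common outcomes this underdispersion biases variance
  components slightly downward (as it would in any BYM analysis of
  proportions).
* Survey weighting, non-response, multiple imputation and the GIS derivation
  of walkability components are out of scope.
* Numerical posterior values of the original analysis are not reproducible
  without its restricted data and sampler internals; validation is therefore
  against oracles and known-truth simulations, not against published
  posterior tables.
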