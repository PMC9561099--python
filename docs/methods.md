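# Methods

## The model

`flockparam` estimates genetic parameters of traits recorded repeatedly on
pedigreed animals under the repeatability animal model

    y = Xb + Za + W_w pe_w + W_y pe_y + e

where `b` are fixed effects (contemporary groups such as birth-year x
birth-flock x sex, plus covariates such as birth-date deviation), `a` are
additive genetic effects with var(a) = A sigma2_a (A the numerator
relationship matrix from the pedigree), the `pe` terms are permanent-
environment effects on animal-level groupings — here a within-measurement-
round term (shared by day 1 and day 2 of a chamber round) and an
across-round/across-year term — each with identity covariance, and `e` is
the residual.  All random effects are mutually independent and Gaussian.

Derived parameters:

- heritability `h2 = sigma2_a / sigma2_p`, with
  `sigma2_p = sigma2_a + sum_k sigma2_pe_k + sigma2_e`;
- repeatability, the intraclass correlation of repeated records on one
  animal: `(sigma2_a + sum_k sigma2_pe_k) / sigma2_p`.  All PE terms are
  included by construction; with both a within-round and an across-round
  term this is the correlation of records in the same round, the quantity
  the published component summaries back-solve to.
- in bivariate fits, genetic / phenotypic / residual correlations from the
  2x2 covariance matrices, e.g. `r_g = sigma_a12 / sqrt(sigma_a11 sigma_a22)`.

Bivariate fits allow the two traits to be recorded on disjoint animal sets
(methane on chamber-measured progeny, maternal traits on adult-ewe
relatives); `r_g` is then identified purely through pedigree relationships,
and the residual covariance — inestimable without co-recorded occasions —
is constrained to zero.  Records of two traits count as co-recorded only
when they share an (animal, occasion) key, or come from the same row of
the same table.

## Pedigree machinery

- A is built by the tabular method (`a_ii = 1 + F_i`,
  `a_ij = (a_{i,s(j)} + a_{i,d(j)})/2`, unknown parents contributing 0);
  unknown parents are unrelated, non-inbred founders.
- Inbreeding is exact, computed in one forward pass through the gene-flow
  decomposition A = T D T' (T the gene-contribution rows, D the
  Mendelian-sampling variances `0.5 - 0.25(F_s + F_d)`, with 0.75 - 0.25 F
  for one known parent and 1 for founders).  The same T rows give
  arbitrary principal submatrices of A without forming the full matrix,
  which is how the REML fitter obtains the relationship block for the
  recorded animals in pedigrees of any size.
- A^-1 is assembled sparsely by Henderson's recursive rules with the same
  D, so it is exact under inbreeding.
- Pedigree files are topologically sorted internally (Kahn's algorithm);
  input row order never matters, cycles and duplicate ids are structural
  errors.

## REML

Variance components maximise the restricted likelihood by average-
information (AI) updates with expectation-maximisation fallback steps.

Two equivalent likelihood evaluations coexist on purpose:

1. `restricted_loglik` factorises the mixed-model equations with a sparse
   LU decomposition, using the sparse A^-1 over all pedigree animals —
   the classical route that scales to deep pedigrees.
2. The fitter works on the marginal covariance
   `V = sum_k Z_k K_k Z_k' Sigma_k + R`.  V is block-diagonal over
   connected components of its sparsity pattern (records linked by a
   shared random-effect level, a nonzero relationship, or a shared
   residual occasion).  For family-structured data the components are
   sire families of a few dozen records, so each block is handled densely
   by Cholesky; likelihood, exact analytic gradients and the AI matrix
   all reduce to small per-block quadratic forms.  This makes exact
   AI-REML cheap without a sparse selected-inverse routine.

Both paths include the full `-(n-p)/2 log 2pi` constant and agree to below
1e-8; the test suite holds them against an independent dense projection-
matrix evaluation.

Numerical choices:

- Parameters are unconstrained: log variances in univariate fits,
  log-Cholesky factors for 2x2 covariance matrices in bivariate fits (so
  estimated matrices are always PSD and correlations stay in [-1, 1]).
  Diagonal-only parameterization for the residual matrix of
  never-co-recorded trait pairs.
- The AI step is ridge-stabilised, capped at 5 units on the log scale and
  step-halved until the likelihood increases; if no AI step goes uphill,
  an EM update (guaranteed non-decreasing) is taken.  Convergence:
  relative likelihood change < 1e-8 and max |gradient| < 1e-4 on the
  unconstrained scale.  Non-convergence is flagged, never silent.
- Variances are floored at 1e-10 of the phenotypic variance; a fit with
  any component at or near this floor (or below 1e-5 of the total) sets a
  boundary flag.
- Identifiability guard: two random terms that induce the same record
  partition with (effectively) identity covariance — e.g. an animal
  genetic term over unrelated animals plus an animal PE term — are
  refused with a clear error rather than returning a ridge solution, as
  is a PE term with one record per level (confounded with the residual).
- Standard errors of components come from the inverse AI matrix at
  convergence, mapped through the parameterization Jacobian; SEs of h2,
  repeatability and correlations follow by the first-order delta method.
  Simulation shows a reported-SE to empirical-SD ratio near 1 (0.9-1.15
  at the scales tested).
- Fixed-effect aliasing is resolved by sequential Gram-Schmidt that keeps
  the earlier column of any dependent set; variance components and their
  ratios are invariant to this choice (tested by record reordering).
  Covariates are centered.  Records missing the response or any model
  column are dropped per trait.

## GLM screening

`screen_fixed_effects` provides the conventional pre-analysis screen of
candidate systematic effects: sequential (type-I) F tests on the
fixed-effects-only model, each term tested against the residual mean
square of the full model, keep at p < 0.05 by default.  It reproduces
statsmodels' `anova_lm` to 1e-8 and shows the nominal type-I error on
pure-noise factors in simulation.

## The synthetic flock generator

There is no public flock data, so validation is by parameter recovery on
synthetic data whose generating process is exactly the model above.

- `simulate_breeding_values` draws founders from N(0, G) and descends the
  pedigree by Mendelian sampling (offspring = parent mean + deviation with
  variance `d_i G`), reproducing cov = A (x) G exactly, including under
  inbreeding, in O(n) — no Cholesky of the full A.
- `simulate_pedigree`/`simulate_records` emulate the study design: sire
  families with 10 chamber-measured progeny each (2 rounds x 2 days,
  contemporary lot/group structure, birth-date covariate), paternal
  half-sib ewes with repeated maternal records at ages 2-6 in multi-flock
  multi-year contemporary groups, lognormal egg counts exercising the
  log_e(x+50) transform, and filter violations (broken seals, feed
  refusals, missing fields) at configured rates.  Raw chamber columns
  (ch4_g, co2_g, dmi_kg, offered_kg) are back-composed from the simulated
  g/day trait so the trait-derivation module reproduces it.
- Default true components are back-solved from the published phenotypic
  SDs, heritabilities and repeatabilities (e.g. CH4 g/d: sigma_p = 2.99,
  h2 = 0.26, repeatability = 0.42 give sigma2_a = 2.32, total PE = 1.43,
  sigma2_e = 5.19).  The split of total PE between the within- and
  across-round terms is not published; the default (0.43 / 1.00) is a
  choice, and only the sum is compared in validation.  Default genetic
  correlations with CH4 g/d follow the published estimates; other pairs
  are uncorrelated.  Contemporary-group effect magnitudes are unreported
  and the defaults (e.g. 1.5 g/d) are order-of-magnitude choices.

What the generator does **not** emulate: voluntary intake variation (the
study fed at twice maintenance), selection-driven allele-frequency change
across generations, overdispersion and zero-inflation of real egg counts,
non-Gaussian threshold structure of litter traits beyond simple rounding /
binomial weaning, and year-to-year environmental trends.  Passing recovery
tests therefore demonstrate correctness of the estimation machinery under
the model's assumptions, not robustness to their violation in field data.

Derived ratio traits (CH4/DMI, molar fraction) inherit their structure
from the composed raw columns and only approximately follow the
repeatability model; exact-model recovery work uses the g/day trait or
`simulate_repeatability_records`, which generates balanced sire-family
data following the model exactly (one or two co-recorded traits).

## Validation problem sizes

Chosen so the whole suite runs in minutes on one CPU:

- Relationship-matrix oracles: 50 random pedigrees up to 200 animals,
  against a memoized recursive-kinship implementation (< 1e-12) and dense
  inversion (< 1e-8).
- Likelihood oracle: 100 random instances up to 50 records and 3 random
  terms, MME vs dense projection (< 1e-8); balanced identity-kinship
  designs against closed-form ANOVA estimators (< 1e-6).
- Univariate recovery: 100 replicates of 100 sires x 10 progeny x 4
  records (h2 = 0.25, repeatability = 0.40); means within +-0.02,
  SE calibration ratio in [0.7, 1.3].
- Bivariate recovery: 50 replicates per true r_g in {0, 0.3, 0.9}; means
  within 2 Monte-Carlo SE.  The 5%-star calibration at r_g = 0 is measured
  over 200 replicates, the sample size at which the +-0.03 acceptance band
  spans two binomial SDs (at 50 replicates the band is one SD wide, so a
  perfectly calibrated test would fail such a check ~18% of the time).
- Pipeline consistency: one full synthetic run — 600 sires x 10 progeny,
  2 rounds x 2 days, contemporary-group effects, filters — generated at
  the back-solved CH4 g/d components; the fitted h2, repeatability and
  sigma_p land within +-0.03 / a few percent of the generating values.
  600 families put the single-run Monte-Carlo SE of h2 near 0.02,
  comfortably inside that demonstration band.

## Shipped model configs

`configs/models/` contains one YAML model spec per panel trait, following
the published final models: methane traits with birth-cohort
(`byr.flk.sex`) and recording (`ryr.lot.group.round`) contemporary groups
plus within-round and across-round PE terms; maternal traits with
`rflk.ryr.mob.ageclass` groups, previous-litter-size, age-of-dam and
birth-rank effects where applicable, and an across-year animal PE term;
single-record egg counts with the genetic term only.  The synthetic
generator emits all referenced factor columns (birth rank and age of dam
carry no simulated effect; they are present so the full fixed-effect
structure is estimable and screenable).

## Known limitations

- Trait pairs are limited to bivariate models; no maternal-genetic or
  dominance effects; no genomic relationships.
- The block-dense fitter is efficient when the record graph decomposes
  (family designs); a single fully connected component of n records costs
  O(n^3) per iteration.  The MME path evaluates likelihoods cheaply in
  that regime but the fitter does not yet use it for updates.
- Wald stars on correlations rely on asymptotic normality; near the
  parameter boundary (|r| ~ 1, components ~ 0) the delta-method SE is
  optimistic.
- Unknown-parent groups are not modelled; all unknowns join one founder
  population.
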