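# Methods

## The screening model

`bfscreen` screens a large panel of candidate factors — individual SNPs, or
genes treated as grouped blocks of SNPs — for association with a
quantitative trait, by Bayesian model selection over a *restricted* model
space: the set of all linear models with exactly `m` active factors out of
`p` candidates.

For a model indexed by the binary inclusion vector γ, the regression is

    y = X_γ β + ε,         ε ~ N(0, σ² I),

with `y` the covariate-residualised trait (mean zero) and `X_γ` the
mean-centred minor-allele-count columns of the active factors.  No intercept
appears because both the response and the design columns are centred.

The conjugate prior

    β | σ² ~ N(0, σ² λ² Σ),      p(σ²) ∝ 1/σ²

integrates out in closed form:

    log p(y | γ) = −½ log|λ²Σ| − ½ log|X'X + (λ²Σ)⁻¹| − (n/2) log Q(γ) + c(n)

with Q(γ) = y'y − y'X (X'X + (λ²Σ)⁻¹)⁻¹ X'y.  The shared constant c(n) is
never evaluated: the sampler and the exhaustive enumerator only ever use
posterior *ratios*.

### Computation

Q(γ) is the residual sum of squares of regressing the augmented response
(y; 0_k) on the augmented design (X; λ⁻¹C) where C'C = Σ⁻¹ (C is the inverse
of the lower Cholesky factor of Σ).  A single QR factorisation of the
augmented design yields both Q and the determinant term (the squared product
of |diag R|), because R'R = X'X + (λ²Σ)⁻¹.  All arithmetic is in log space:
with n near 700, Q^(−n/2) would underflow any floating-point format.

Because the prior precision is added to X'X, the augmented design always has
full column rank: duplicate columns, and columns that are all zero after
centring (monomorphic variants), are well posed.  A zero column triggers a
warning, not an error.  Near-perfect fits are guarded by flooring Q at the
smallest positive float before taking the log.

The closed form is verified two independent ways in the test suite: against
direct numerical quadrature of the double integral (tensor Gauss–Legendre
after substituting u = log σ² and β = λ√σ²·t, so a fixed unit-scale t-grid
covers every variance slice), and by recomputing Q and the determinant from
explicit normal equations.

### Model priors

* SNP mode: every model has exactly `m` columns, so all models share one
  prior probability and the posterior ratio is the evidence ratio.
* Gene mode: the number of columns k varies with the active genes, and a
  uniform model prior would favour variant-rich genes.  The size-penalised
  prior weights a model by exp(−k/2), k the number of regression
  coefficients.  This deliberately reproduces the known overcorrection of
  this penalty toward small genes; a BIC-style exp(−(k/2)·log n) variant is
  available behind the `bic_log_n` flag but is off by default.  k counts
  design columns only (the dimension of β, not σ²); since only differences
  in k enter the ratios, the additive convention is immaterial.

## The sampler

A Metropolis–Hastings chain over m-subsets: each step swaps one uniformly
random active factor for one uniformly random inactive factor, a symmetric
proposal with probability 1/(m(p−m)) in both directions, so the acceptance
probability is min{posterior ratio, 1}.  A proposal with a non-finite log
posterior is auto-rejected.  The initial state is a uniformly random
m-subset from the seeded generator; the chain is deterministic given its
seed.

Marginal inclusion probabilities are visit counts: the fraction of
post-burn-in iterations in which a factor is active, repeated states counted
every iteration.  They therefore sum to exactly m.  Evidence values are
cached per model (bounded LRU keyed on the sorted active set), so revisits
cost a dictionary lookup.

Defaults follow the study design the method targets: 100,000 iterations
after 1,000 burn-in at SNP level, 10,000 after 1,000 at gene level, m = 10
(SNP) and m = 3 (gene), λ = 1 (effects of order one), Σ = I.  At gene level
an exchangeable Σ with within-gene correlation 0.1 is available; in practice
its results are close to the identity prior.

Convergence is assessed, never gated: running two chains from different
seeds and correlating their inclusion vectors (Pearson by default, Spearman
exposed).  The CLI prints the correlation and warns below 0.9.

## The synthetic study generator

The generator emulates the structure of a GAW17-style mini-exome study so
the full pipeline can be exercised with known truth:

* 697 unrelated individuals, 200 genes by default (~1,000 variants; a
  full-scale preset with 3,205 genes / ~24,500 variants and 39 causal
  variants in 9 genes exists for manual runs);
* gene sizes geometric with mean 5, capped at 40 — highly variable counts;
* MAFs from 0.5·Beta(0.3, 3), floored at one copy — a rare-skewed spectrum
  (realised median ≈ 0.015) with occasional common variants;
* genotypes binomial(2, MAF) independently per individual and site;
* 10 causal variants in 4 genes with effects
  (1.35, 0.9, 0.7, 0.55, 0.5, 0.4, 0.3, 0.2, 0.15, 0.13) paired with MAFs
  (0.25, 0.15, 0.10, 0.08, 0.07, 0.02, 0.01, 0.005, 0.003, 0.002): the
  effect range matches the trait model the screen targets, and the pairing
  spans clearly-detectable common signals down to undetectable private ones;
* covariates Smoke ~ Bernoulli(0.25) (coefficient 0.3), Age ~ U{20..80}
  (0.01), Sex ~ Bernoulli(0.5) (0.2); noise N(0, 1).  These give a trait
  with heritability ≈ 0.5, dominated by the common causal variants;
* optional smoking × causal-gene-burden interaction with a single
  multiplier, off by default.

What the generator does **not** emulate: linkage disequilibrium from real
haplotypes (an optional Gaussian-copula within-gene LD mode exists for
robustness experiments but is beyond the emulated design), population
structure, pedigrees, or the actual GAW17 trait model.  Passing recovery
tests on this generator therefore demonstrates correctness of the screen
under independent-site genotypes with the stated architecture — not
performance on LD-structured real exomes, where correlated neighbours of a
causal variant share its signal.

The trait decomposes exactly into genetic + covariate + interaction + noise
parts, stored in the truth ledger for tests and reports.

## Covariate adjustment

Covariate effects are removed once, up front, by OLS of the trait on an
intercept plus the covariates; the residuals are the screening response.
This two-stage scheme (rather than carrying covariates inside every model)
keeps the per-model computation minimal, at a known cost: genotype ×
covariate interactions are not modelled, which lowers power for genes whose
effect acts through such an interaction.  The covariate design is checked
for full rank with a pivoted QR so a collinear column can be named.

## Numerical and design choices

* Minor allele decided per site from the loaded sample; an ALT frequency of
  exactly 0.5 counts ALT as minor (deterministic tie rule).  This makes the
  genotype matrix invariant to REF/ALT labelling.
* Missing genotypes are a hard error — the method assumes complete data and
  silent imputation would bias MAFs.
* Ranking ties break by factor id (posterior descending, id ascending), so
  reports are byte-reproducible under a fixed seed.
* The false-positive discovery rate reported is the realised proportion
  FP/(FP+TP) among factors above a posterior cutoff given known truth — a
  realised false-discovery proportion, not an expected FDR.
* Problem sizes in the test suite and acceptance script are the generator's
  default replicate (n = 697, ~1,000 variants) with 50,000-iteration SNP
  chains and 10,000-iteration gene chains over 10 replicates, plus the
  defaults-length (100,000) two-chain comparison — the same study
  conditions scaled to a single-workstation run.

## Known limitations

* Rare causal variants (MAF below a few percent) are rarely recovered at
  n ≈ 700 — an inherent power limit of the design, reproduced faithfully by
  the recovery tests rather than worked around.
* The exp(−k/2) gene prior overcorrects toward variant-poor genes; it is
  kept as-is because it is the method under study.
* Factor–factor interaction terms are not included in the model matrix.
* The sampler is single-chain per run (two chains only as a diagnostic);
  no tempering or adaptive proposals.
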