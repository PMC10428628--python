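# Methods

This note records the modeling choices, default parameters and numerical
conventions behind `maizegp`, and what the synthetic panel does and does not
emulate.

## Synthetic panel

The generator (`maizegp.simulate`) produces fully homozygous inbred lines
(dosages 0/2; heterozygotes are accepted everywhere downstream but never
emitted). Defaults mirror the study panel scaled down in marker count:
258 lines in two subpopulations of 83 and 175, ten chromosomes, 3,000
markers spaced ~3.3 kb apart, four environments, three traits.

* **Population structure** follows the Balding–Nichols model: ancestral
  frequency `p ~ U(0.1, 0.9)` per marker, subpopulation frequencies
  `Beta(p(1−F)/F, (1−p)(1−F)/F)` at divergence `F` (default Fst = 0.1).
* **Linkage disequilibrium** comes from a Gaussian-copula AR(1) process
  along each chromosome: the latent correlation between adjacent markers is
  `exp(−d/L)` for spacing `d` and block length `L` (default 50 kb), and the
  latent variable is thresholded at `Φ⁻¹(p)` so marginal allele frequencies
  are preserved exactly. This yields distance-decaying pairwise r² without
  coalescent machinery; it does not produce realistic haplotype block
  boundaries, recombination hotspots, or allele-frequency/LD correlations,
  so passing tests speak to the statistical machinery, not to any specific
  maize genome.
* **Traits.** FF and MF share one QTL set (default 150 QTL) with effects
  drawn from a bivariate normal at the configured genetic correlation
  (default 0.85); genetic values are rescaled to a genetic SD of 3 days
  around base means of 67 (FF) and 65 (MF) days plus per-environment
  offsets. G×E is generated as per-environment perturbations of the QTL
  effects, scaled so var(G×E)/(var(G)+var(G×E)) equals
  `gxe_variance_share` (default 0.2) within an environment; the FF and MF
  perturbations are drawn with the same correlation as the main effects —
  independent draws would dilute the within-environment trait correlation
  by a factor (1 − share). Residual noise is scaled against the *realized*
  per-environment genetic variance so plot-level narrow-sense h² matches
  its target (defaults 0.72 for FF, 0.66 for MF) up to sampling error. ASI
  is emitted record-wise as MF − FF; its low heritability (≈ 0.3) is
  emergent from the high FF–MF correlation, not imposed. Replicate and
  block-within-replicate effects are i.i.d. normal (default SD 0.3 days
  each, zero in the noiseless h² = 1 limit) so the adjustment model has
  design effects to remove.

The simulation truth (QTL positions and effects, per-line genetic values
per environment, realized variance components) is stored alongside every
phenotype set for parameter-recovery tests.

## Preprocessing

QC removes markers in a fixed order — monomorphic (fewer than two distinct
observed calls; all-missing markers fall here), call rate < 0.90, then
MAF < 0.05 computed on non-missing calls with a strict inequality — and is
idempotent. LD-kNN imputation selects, per missing cell, the `l = 30`
markers in highest r² with the target marker that are observed in the
focal line, measures an r²-weighted Euclidean distance to every line
observed at the target, and lets the `k = 5` nearest lines vote for
{0, 1, 2} with inverse-distance weights (distance floor 1e−6; ties broken
by line index). The r² weighting matters: unweighted distances let weakly
linked markers drown out a perfectly linked one.

Kinship comes in two flavors: IBS (`K_ij = mean(1 − |d_i − d_j|/2)`,
diagonal 1) for the GWAS, and the VanRaden genomic relationship
`G = WWᵀ / (2Σp_j(1−p_j))` with `W = D − 2p` for the prediction models.
For fully inbred lines the VanRaden diagonal averages `1 + F ≈ 2`; the
heritability reported from a fit is therefore
`h² = c·σ²_u / (c·σ²_u + σ²_e)` with `c` the mean diagonal of the kinship
used, stored at fit time.

Pairwise LD is the squared Pearson correlation of dosage columns
(pairwise-complete via indicator algebra). The critical (background) r² is
the square of the 95th percentile of √r² over inter-chromosomal pairs,
subsampled to ≤ 50,000 pairs with a fixed seed; returning the value on the
r² scale matches the convention of quoting a single r² cut-off. The decay
distance is the midpoint of the first distance bin (default width 500 bp
in the library, 2 kb in the analysis scripts, matched to marker spacing)
whose mean intra-chromosomal r² falls below the critical value; a curve
that never crosses is flagged `nan`. Candidate windows around GWAS hits
span twice the decay distance, centered on the SNP, clamped at position 1;
coordinates are 1-based closed intervals internally and convert losslessly
to 0-based half-open BED.

## Phenotype adjustment

Per environment and trait, `y = Xβ + Zf + ε` is fit by Gibbs sampling with
replicate and block-within-replicate fixed and line effects random
(identity covariance); the adjusted value is the grand fixed-effect mean
plus the posterior-mean line effect. The variance priors are scaled
inverse-chi-squared with the scale set from the *design-adjusted* (OLS
residual) variance, which makes the adjusted values invariant to additive
replicate offsets. Environments where every line has a single record are
passed through unchanged (no design effect is estimable). Because the
line effects are posterior means, adjusted values are shrunken BLUPs;
variance ratios re-estimated on them (the second stage) are on the
entry-mean basis and exceed plot-level heritabilities — expected behavior
of a two-stage pipeline, worth remembering when comparing h² numbers.

## The three Gibbs samplers

All samplers share conventions: chain defaults 100,000 iterations, 10,000
burn-in, thinning 5 (`MCMCSettings`); the test suite and the reduced
analyses run scaled-down chains (5,000/1,000/2 or 1,500/400/2). A draw is
stored when `(iteration − burn_in) mod thin == 0`, giving
`⌊(n − burn)/thin⌋` draws. Kinship matrices receive one shot of jitter
(1e−8 × mean diagonal) before eigendecomposition; failure after jitter is
an error. A split-chain potential-scale-reduction factor is computed for a
monitor variance component and logged (warns above 1.1, never fails).
Weakly informative priors: inverse-Wishart with ν = t+1 and scale
0.1 × diag(var(y)) for trait covariances; scaled inverse-chi-squared with
ν = 5 and scale set to half the data variance (split across kernels) for
the G×E model.

**Multi-trait mixed model.** The random effects are sampled in the
eigenbasis of A, where lines decouple into t×t solves (batched). With
`fix_variance=(G0, R0)` the covariance updates are skipped and the
posterior mean equals the exact MME solution — the oracle-equivalence
test. Intercept-only fixed effects per trait; the model is fit per
environment.

**G×E kernel model.** Kernels are eigendecomposed once with negative
eigenvalues truncated at zero; zero-eigenvalue directions carry no effect
by construction. Missing records (the prediction targets in
cross-validation) are data-augmented each sweep from the current fit, so
posterior-mean fitted values at those records are genuine out-of-sample
predictions. Fixed effects are per-environment means.

**Matrix-variate multi-trait multi-environment model.** Two
identifiability problems must be solved before a conditional Gibbs sampler
on (β, b₁, b₂, Σ_t, Σ_e, R_e) is stable, and neither is visible in the
model statement alone:

1. Environment-constant components of the interaction b₂ are
   indistinguishable from the main effect b₁, and the unidentified
   direction random-walks while the covariance updates chase it. b₂ is
   therefore parameterized on an orthonormal sum-to-zero contrast basis
   across environments (a QR-orthonormalized centering matrix), making
   Σ_e the (e−1)×(e−1) covariance of interaction contrasts; with a single
   environment the interaction term vanishes entirely.
2. The scales of Σ_e and Σ_t are jointly unidentified in b₂'s prior
   (c·Σ_e with Σ_t/c gives the same law); Σ_e is renormalized to trace e
   after each draw so the magnitude is carried by Σ_t, which is anchored
   by both genetic terms.

Genetic effects are restricted to the column span of G (eigenvalues below
1e−8 of the maximum truncated), which keeps the inverse-Wishart
degree-of-freedom counts equal to the number of sampled directions.
Missing cells are data-augmented row-wise from the conditional normal
under R_e; an environment with no observed cells keeps its intercept
pinned at the grand mean (predictive correlations are unaffected by the
per-environment constant). Update order per sweep:
augmentation → β → b₁ → b₂ → Σ_t → Σ_e → R_e.

## Feedforward network

Inputs are `X = [Z_E, Z_G Qᵀ, Z_GE (I_e ⊗ Qᵀ)]` with `G = QᵀQ` (upper
Cholesky; jitter rule as above), environment- and line-levels sorted
lexically and G×E columns environment-major (`col = env_index·g +
line_index`). The identity `(Z_G Qᵀ)(Z_G Qᵀ)ᵀ = Z_G G Z_Gᵀ` is
property-tested. The network has three hidden ReLU layers of 50 units and
one output per trait; training minimizes mean squared error (unweighted
mean across traits) with Adam at rate 1e−3, full batch below 1,024
records, 200 epochs by default (50 in the reduced analyses), inverted
dropout 0.2 on hidden layers during training only. Targets are z-scored
per column on the training fold and de-standardized at prediction; input
columns are left unscaled because the three blocks are already on
comparable scales. He-style initialization from a seeded generator makes
training bit-reproducible single-threaded. The uni-trait mode is the same
architecture with output width 1. Which relationship matrix feeds the
Cholesky is a free choice; VanRaden is used, matching the matrix-variate
model.

## Cross-validation

Splits are at the line level (a line's records move together) and shared
across traits and approaches within a cycle, so uni-/multi-trait
comparisons use identical folds. In scenario I the validation lines are
held out in the environment under evaluation; for multi-environment
approaches their records in other environments stay in training (the
common incomplete-field-trial prediction setting), switchable to full-line
holdout. Model/approach eligibility: the multi-trait mixed model serves
UTUE/MTUE, the G×E kernel model UTME, the matrix-variate model MTME, and
the network all four. Scenario II names training sets DT1 (one earlier
environment; uni-environment models transfer genotype effects), DT2 and
DT3 (multi-environment models treat the target environment's cells as
unobserved). Accuracy cells are compared across models by the
Tukey–Kramer honestly-significant-difference test on per-cycle accuracies
(α = 0.01 default) with an insert-and-absorb compact letter display;
relative improvement between approaches is
`100·(mean_B − mean_A)/mean_A` over matched environment × trait cells.
Each cycle derives its chain and network seeds from the scheme seed
through a `SeedSequence` spawn, so whole tables are bit-reproducible.

## GWAS, Bayes factor, PPA

Structure covariates are the top principal components of the centered
dosage matrix (default 2, matching the two-subpopulation panel). Variance
components of the null model `y = X₀β + u + ε`, `u ~ N(0, σ²_g K)`, are
estimated once by maximum likelihood through the spectral decomposition of
K (bounded scalar search over log(σ²_e/σ²_g)); each marker is then tested
by GLS on the whitened data via Frisch–Waugh residualization, a Wald t
with df = n − p₀ − 1, all markers vectorized in one pass. Markers
collinear with the covariates are flagged NA and the scan continues.
PV% (variance explained) is the partial R² of the 1-df marker term,
`100·F/(F + df_resid)`. The default reporting threshold is p < 2e−5,
exposed as a flag; π for the PPA defaults to the same threshold.

The pleiotropy Bayes factor compares `Y = 1μ + x m + E` against `m = 0`
for the centered two-trait response under a conjugate
matrix-normal–inverse-Wishart family: both models share a vague intercept
precision (1e−6) and the residual prior IW(q+2, diag(var(Y))), and the
alternative puts a unit-information-style precision `xᵀx/(n·scale²)` on
the marker row (default scale 1). Marginal likelihoods are closed-form
(matrix-t); as the prior scale shrinks to zero the BF tends to 1, the
Occam limit. PPA = BF·π/((1−π) + BF·π), strictly increasing in both
arguments.

## Problem sizes and reduced defaults

The package's full-scale defaults (100k-iteration chains, 50 CV cycles,
200 epochs) match the study protocol; the shipped analyses and the
acceptance script run a reduced configuration chosen to keep a complete
pipeline execution in the minutes range on one CPU: 3,000 markers instead
of ~290k, 3 CV cycles over two environments with 1,500-iteration chains,
and 50-epoch networks. All reductions are configuration values, not code
paths; `analysis/04_cross_validate.py --full` restores the full protocol.

## Known limitations

* The LD model is stationary within chromosomes; no recombination-map or
  ascertainment realism, and no minor-allele-frequency/LD coupling.
* The generator's G×E (correlated per-environment effect perturbations) is
  one of many possible generative choices; environment-specific variance
  heterogeneity is not simulated.
* REML is not implemented; the GWAS null model uses ML variance
  components, slightly downward-biased in σ²_g for small n.
* Two-stage heritabilities (on shrunken adjusted values) are entry-mean
  quantities; they are reported as computed, not mapped back to plot
  level.
* With very short chains the variance components of low-signal traits mix
  slowly; the split-R̂ log warning flags this, and longer chains are one
  configuration flag away.
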