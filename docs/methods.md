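# Methods

## The prediction problem

A breeding consortium accumulates phenotypes for hundreds of genotypes
across many locations and years, but the incidence is sparse: any one
genotype is grown at a handful of locations for a couple of years. `envgp`
targets the third classical MET cross-validation scenario — predicting
*observed genotypes in an unobserved location* — and compares three ways of
spending the training data: pooling it into one model (singular), training
one submodel per training location and averaging predictions (environment
ensemble), and pruning that ensemble by validation accuracy (optimized
ensemble).

## Synthetic MET generator

The generator is a forward model of the per-location decomposition used by
the estimators downstream:

    y_ilk = m_l + (X u_l)_i + s_lk + e_ilk

* **Markers.** Unlinked Hardy–Weinberg dosages coded 0/1/2 as copies of the
  major allele; each marker's minor allele frequency is drawn uniformly on
  `maf_range` (default 0.05–0.5). Columns whose realized MAF falls below
  half the range minimum are resampled (at most 100 times). Linkage
  disequilibrium, population structure and non-additive effects are out of
  scope: the pipeline's statistics operate on an additive signal and the
  tests need a controllable one, not a population-genetically realistic one.
* **Genotype-by-environment interaction.** Per-location marker effects mix a
  shared and a location-specific standard-normal vector,
  `u_l ∝ d_l (√ρ s + √(1−ρ) t_l)`, so `ρ ∈ [0,1]` is the genetic correlation
  between any two locations (ρ = 1 gives identical genetic values
  everywhere) and `d_l ≥ 0` scales how strongly location l separates
  genotypes. Effects are rescaled so the realized genetic standard deviation
  over all genotypes at a location with d = 1 equals `genetic_sd` exactly;
  this makes the discriminativeness knob strictly monotone in the realized
  genotypic variance under a fixed seed.
* **Design.** Each genotype is assigned a uniform random subset of
  `mean_locations_per_genotype` locations (default 6 of 18) and grown for
  `years_per_genotype_location` consecutive years (default 2 of 10),
  emulating a nursery where an entry circulates for a short period. The
  design is redrawn (≤ 100 times) until every location keeps ≥ 2 genotypes.
* **Noise back-solved from heritability.** Years within a location are
  exchangeable Gaussian effects (`year_effect_sd`, default 0.2). The
  residual variance at each location is back-solved from the target
  broad-sense heritability via `σ²_e = σ²_g (1−H²)/H² − σ²_y`, floored at
  1e-8 with a warning, where σ²_g is the realized genetic variance among the
  genotypes actually grown there. Plugging back in gives
  `σ²_g/(σ²_g+σ²_y+σ²_e) = H²` exactly. H² = 0 with genetic signal and
  H² = 1 with year variance are rejected as unsatisfiable. Default targets
  span 0.05–0.95 across locations, the range real per-location
  heritabilities cover for a single trait.
* **Heritability–discriminativeness coupling.** `h2_profile_constant_noise`
  builds the profile implied by constant absolute noise
  (`H²_l = d²_l g² / (d²_l g² + σ²_y + σ²_e)`): a wide per-location H² range
  for one trait is usually noise-driven, with measurement error roughly
  constant in trait units while genotypic variance varies. Controlled
  sweeps that vary discriminativeness alone instead hold H² fixed, so only
  one factor moves.

The full truth channel (effect vectors, location means, year effects,
per-record residuals) is returned, and the conservation identity
`value − (location mean + year effect + residual) = genetic value` holds to
1e-10, which downstream parameter-recovery tests rely on.

## BLUEs and variance components

Genotype adjusted means at each location come from a REML fit of the
fixed-genotype / random-year-intercept model (statsmodels `MixedLM`,
genotype in cell-means coding so coefficients are the adjusted means).
Because a fixed effect has no variance component, σ²_g comes from a
companion fit of the same records with genotype *and* year as variance
components (single grouping, REML); σ²_e is the residual. Single-year
locations fix σ²_i = 0. Numerical choices:

* The response is standardized inside the variance-component fit and the
  components mapped back by the squared scale, making H² exactly
  scale-invariant.
* Optimizers are tried in the order lbfgs → cg → powell; non-convergence
  raises with the diagnostics attached (the table-level driver degrades to
  BLUEs-only with a warning).
* Degenerate slices (constant records, or an exactly saturated two-way fit)
  bypass REML: adjusted means come from minimum-norm least squares with
  sum-to-zero year coding, which equals the mixed-model answer on balanced
  data, and components are set to zero.
* Negative component estimates are truncated at zero with a warning.

On balanced data the REML estimates coincide with the closed-form ANOVA
method-of-moments estimators; the test suite uses that identity as an
independent oracle, and recovery on 200 genotypes × 5 years at a target
H² of 0.5 is accurate to well within ±0.07 over 20 seeds.

## Base models

* **OLS** — minimum-norm least squares on centered features (`lstsq`);
  rank-deficient systems therefore return the smallest-norm coefficient
  vector.
* **Ridge** — closed-form `(XᵀX + λI)⁻¹Xᵀy` on centered features with the
  intercept unpenalized. λ is chosen per training set by 3-fold CV Pearson
  accuracy over the log grid {0.01, 0.1, 1, 10, 100, 1000}; ties keep the
  first (smallest) λ. The grid-and-CV policy is this package's design
  choice; a closed-form oracle and scikit-learn's `Ridge` serve as
  independent checks in the tests.
* **Network** — a NumPy multilayer perceptron: ReLU hidden layers of one
  shared width, linear output, inputs standardized with training-block
  statistics, He-style scaled-uniform fan-in initialization, minibatch Adam
  (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) on mean-squared error. Training stops
  when the epoch-loss history is convex over its last three entries
  (consecutive decrements positive and shrinking — three epochs is the
  smallest window that defines curvature) *and* the last relative decrease
  is under 5%, or at 50 epochs. Hyperparameters are drawn from log10-uniform
  learning rate on [1e-4, 100], log2-uniform batch size on {4,…,128},
  uniform depth on [3,8] and width on [3,100], ranked by mean 3-fold CV
  accuracy; divergent draws (non-finite loss) score −∞ and are skipped.

## Training regimes and optimization

Ensemble predictions are always the unweighted arithmetic mean of submodel
predictions. Network ensembles use environment bagging: each submodel
trains on L location blocks drawn with replacement from the L training
locations, matching the extra data volume networks need. The optimized
ensemble screens submodels by single dropout judged against the full
ensemble's validation accuracy (not sequentially), excluding a submodel iff
dropping it *strictly* raises accuracy; ties conservatively keep data. If
everything would be excluded, the single most valuable submodel is
retained with a warning.

The validation set is, by default, a genotype-stratified 20% holdout carved
from the training locations' rows — held-out genotypes are removed from
every training block, so no genotype straddles the split and the test
location never informs any training decision. Screening runs on
holdout-reduced submodels; survivors are refit on their full blocks. A
`leaky` mode scores dropouts on the test location itself, provided
because the optimization protocol it replicates can be read that way; every
manifest labels which mode produced it.

## Evaluation

Leave-one-location-out CV trains every approach × base on the remaining
locations and scores Pearson correlation against the held-out location's
BLUEs. Folds are seeded from the run seed and the test-location *name*, so
fold order cannot change any number. Undefined correlations (constant
vectors) are recorded as missing, never as zero, and excluded from means.
The variance-threshold statistic sorts a trait × base combination's
locations by phenotypic variance (sample variance of the location's BLUEs)
and reports the largest variance v\* such that the ensemble beats the
singular model at every location with variance ≤ v\*, as a percentage of
the maximum variance; the overall statistic averages defined combinations.
The exact rule is this package's operationalization of a threshold that can
be defined several ways, so the per-combination values are emitted
alongside.

## GGE geometry

The genotype × environment cell matrix holds one BLUE per cell;
environments with fewer than two observed genotypes are dropped, and
missing cells are filled with the environment mean (zero after centering),
with the fill fraction reported so heavy sparsity is visible. After
environment-centering, the SVD's component signs are fixed so each
component's largest-magnitude environment loading is positive. Under
environment-focused partitioning (the default; environment geometry is what
gets read), environment scores are VS and genotype scores U, so full-rank
environment-score inner products equal the centered cross-product matrix —
the identity that justifies reading vector length as discriminativeness and
vector angle as environment correlation. Two components are kept for
geometry; all are retained internally.

## What the synthetic testbed does and does not show

Passing tests demonstrate that every estimator recovers what the generator
planted: heritabilities, discriminativeness orderings, correlation
structure, and the algebraic identities of the ensemble machinery. The
generator's locations are exchangeable given (d_l, H²_l) and share a single
between-location correlation ρ. Real METs are not exchangeable — specific
locations correlate with specific others — and one documented consequence
is that the sign pattern of the ensemble-minus-singular accuracy gap across
a discriminativeness sweep is *not* reproduced here: pooled least squares
and prediction-averaged per-location fits share the same amplitude-weighted
expected effect direction under this generative family, so their mean
accuracy gap hovers near zero at every test location rather than favoring
the ensemble at low-discriminativeness locations. The corresponding
acceptance test states the expected field behavior and is allowed to fail
on the synthetic testbed; the acceptance script reports the measured gaps
at both extremes so the magnitude is visible.

## Problem sizes

Test and script runs use desk-scale versions of the study design: 40–200
genotypes, 60–400 markers, 3–8 locations, 2–5 years, 15–50 selected SNPs,
network tuning budgets of 4–30 random draws (300 remains available via
`--full-scale`/`full_scale`). These sizes keep every statistical check
comfortably powered for the effects the generator plants while the whole
suite runs in minutes.
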