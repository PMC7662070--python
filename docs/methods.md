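# Methods

`plsgp` implements multi-trait genomic prediction in which markers are
prioritized by two-block canonical partial least squares (PLS-CA) before
entering a weighted genomic relationship matrix, and breeding values are
estimated by Bayesian multi-trait GBLUP via Gibbs sampling.  This note
records the models, the numerical choices, and what the synthetic data do
and do not emulate.

## Models

### Phenotype correction

Raw field measurements are corrected for experimental design by ordinary
least squares per trait, `y = Xβ + e`, where `X` holds an intercept and
dummy-coded design factors (replicate, block nested within replicate,
seed-orchard set).  Two outputs are supported:

* *residual + intercept*: the corrected observation `β₀ + ê`, averaged to
  one record per genotype when clonal ramets exist;
* *genotype BLUEs*: fixed genotype effects re-centered on the grand mean
  (used for clonally replicated trials).

Nested factors are handled by fitting the innermost factor only (a block
label encodes its replicate); fitting both produces an aliased design and
a deliberate error naming the aliased columns.

### Relationship matrices

* Pedigree `A` by the recursive tabular method: founders have diagonal 1
  and mutual 0; `a(i,j) = ½(a(j,s) + a(j,d))`, `a(i,i) = 1 + ½a(s,d)`;
  an unknown parent contributes 0.
* VanRaden `G = ZZ′ / (2Σᵢ pᵢ(1−pᵢ))` with `Z = M − 2p`, `p` the
  alternative-allele frequency of the analyzed sample.  Frequencies are
  always computed from the analyzed sample; no reference population is
  assumed.
* Weighted `G_w = ZWZ′ / Σᵢ wᵢ` for a diagonal, nonnegative weight matrix
  `W`.  With the 0/1 weights produced by marker selection this is the
  cross-product over selected markers divided by their count.  Note the
  denominator deliberately carries no heterozygosity term, so `G_w` is on a
  different scale from `G` (its mean diagonal is roughly the mean `2p(1−p)`
  of the selected markers).  Correlation-based quantities (prediction
  accuracy, matrix correlations) are invariant to this scale; variance
  components from `G_w` are not, and an optional `vanraden_scale` flag
  restores VanRaden's denominator over selected markers if comparable
  variance components are wanted.
* Matrices are made factorizable by adding a recorded diagonal jitter when
  the smallest eigenvalue falls below 1e-8 (G is rank-deficient whenever
  markers < individuals); the jitter is `1e-6 + max(0, −λ_min)`.
* Matrix correlations (used to compare selected-marker kernels with the
  all-marker kernel) are Pearson correlations over the lower triangle
  *including* the diagonal.  The element set is a package decision; the
  off-diagonal-only variant gives very similar values on family data.

### PLS-CA marker prioritization

With column-standardized marker block `X` (n × m) and trait block `Y`
(n × t), component k solves

    max Cov(X_k u, Y_k v),   ‖u‖ = ‖v‖ = 1,

whose solution is the leading singular pair of `X_k′Y_k` (computed in the
t × t space, so m can be large).  Both blocks are then deflated on their
*own* latent scores (canonical mode), which makes latent scores orthogonal
within each block — verified to 1e-8 in the tests.  Signs are fixed by
requiring the largest-magnitude entry of `v_k` to be positive, making
selection tails reproducible across platforms.

Selection truncates the loading vector `u_k` at an empirical percentile
with linear interpolation at position `h = 1 + (p/100)(n−1)` and includes
every loading ≥ the threshold (ties included).  For distinct loadings the
selected count is therefore `n − ⌈h⌉ + 1` when `h` is integral and
`n − ⌊h⌋` otherwise — this closed form reproduces the reference
single-component counts for marker panels of 9,697 and 58,636 SNPs at all
five percentiles (90…50).  One-tailed selection keeps the upper tail only
(positive pleiotropy); two-tailed selection adds the mirrored lower tail
at `100 − p` (negative pleiotropy; at p = 50 the tails meet and every
marker is selected).  Multi-component scenarios take the union of the
per-component selections and binarize to 0/1 weights.  The symmetric
two-tailed rule is a package decision: the reference two-tailed counts are
not consistent with any symmetric tail rule, so only one-tailed counts are
treated as exactly reproducible.

### Bayesian multi-trait GBLUP

The multivariate model is `Y = XB + a + e` with
`vec(a) ~ N(0, Σ_a ⊗ K)` and `vec(e) ~ N(0, Σ_e ⊗ I)`, for a relationship
kernel `K` (A, G or G_w) and trait-wise intercepts by default (phenotypes
are pre-corrected).  Gibbs full conditionals:

* `B`: matrix-normal (flat prior);
* `Σ_a`, `Σ_e`: inverse-Wishart, `IW(ν_a + n, S_a + Ã′D⁻¹Ã)` and
  `IW(ν_e + n, S_e + E′E)`, where `Ã = U′a` lives in the eigenbasis
  `K = UDU′`;
* breeding values: after rotating individuals into the kernel eigenbasis,
  the (Σ_a, Σ_e) pencil is diagonalized each iteration
  (`Σ_e = LL′`, `L⁻¹Σ_aL⁻ᵀ = QΛQ′`), leaving one scalar Gaussian full
  conditional per individual × trait-eigen coordinate with posterior
  variance `dᵢλ_k/(1 + dᵢλ_k)`.  This is exact given the current
  covariances and fully vectorized; the tests verify agreement with a
  naive joint multivariate-normal sampler on small instances.
* missing phenotype cells are data-augmented from their conditional normal
  given the observed cells of the same individual.  Cross-validation
  masking is therefore exact: a masked individual's GEBV is informed only
  through relatedness.

Priors default to `ν_a = ν_e = t + 2` with scale matrices
`S = diag(f · var_p) · (ν − t − 1)` splitting the phenotypic variance
evenly (`f = 0.5` each) — weakly informative and proper.  The univariate
sampler is the t = 1 case with scaled-inverse-χ² variance updates, plus an
optional i.i.d. random effect (block within replicate) for analyses of raw
observation-level data; clonal ramets are supported when replication is
balanced (the generator produces balanced ramets; unbalanced field data
should be pre-corrected to genotype level first, which is the intended
two-stage flow).

Heritability `h² = σ_a²/(σ_a² + σ_e²)` and genetic correlations
`r_G = σ_axy/√(σ_ax²σ_ay²)` are computed **per retained sample** and then
summarized; sample-wise summaries propagate uncertainty correctly and
differ from ratios of posterior means on skewed posteriors (asserted in
the tests).  Because every retained `Σ` draw is positive definite, h² and
r_G are bounded by construction; credible intervals are central 95%.  As a
consequence the intervals cannot go below 0 for h², unlike
likelihood-based intervals which may.

DIC uses the **conditional** deviance `D(θ) = −2 log p(Y | B, a, Σ_e)`
over observed cells, `DIC = 2·mean(D) − D(θ̄)` with `θ̄` the posterior
means — matching the reporting convention of the Gibbs-sampling mixed-model
software family this engine mirrors, and stated explicitly because the
marginal-likelihood DIC differs.

Chain defaults are desk-scale — 20,000 iterations, 5,000 burn-in,
thinning 10 (1,500 retained draws) — chosen so a full scenario grid runs
on a laptop; effective-sample-size diagnostics for h² are reported with
every fit.  Production-scale settings (e.g. 300,000 / 50,000 / 10) are
plain configuration overrides.

### Cross-validation and scenario comparison

k-fold (default 10) random partitions with sizes differing by at most one.
Within each fold, PLS-CA is fit on **training individuals only** (a hard
leakage guard asserts no validation row reaches the selection step;
markers monomorphic within a training fold get weight 0), `G_w` is built
over all individuals, and the multi-trait sampler runs with validation
phenotypes masked.  Accuracy per trait = Pearson correlation between
reference values and cross-validated GEBVs, computed per fold then
averaged; the across-fold SD is the reported spread.  On synthetic data
the reference is the true breeding value; on real data the EBVs from the
full-data pedigree-based multivariate model (both are exposed; the
defaults are as stated).

Scenario grids cover univariate BLUP/GBLUP, multivariate MVBLUP/MVGBLUP
and every mode × percentile × components cell; ranking uses DIC from the
full-data (non-CV) multivariate fit.  Paired scenario comparisons use a
Wilcoxon signed-rank test on per-fold accuracies: zero differences
dropped, ties mid-ranked, exact null distribution by dynamic programming
over doubled ranks for n ≤ 25, normal approximation with continuity and
tie corrections above.

## Synthetic data generator

The generator emulates the two tree-breeding population types the method
targets: full-sib families from pair crosses among founders (clonally
replicable) and open-pollinated half-sib families whose pollen parent is
an anonymous draw from the founder allele pool (recorded as unknown in the
pedigree).  Founder genotypes are binomial(2, p) with p ~ U(0.05, 0.5) by
default; offspring are produced by Mendelian gene dropping at **unlinked**
loci.  Family co-segregation is therefore the only relatedness signal —
deliberate, because the prediction machinery exploits family structure,
not linkage maps.  Consequences: no LD between markers and QTLs beyond
co-segregation, so passing tests demonstrate family-driven prediction, not
LD-driven persistence of accuracy across unrelated material.

Trait architecture: `n_qtl` markers are causal.  A fraction π of QTLs
(default 1) is pleiotropic with effect rows drawn from a multivariate
normal whose correlation matrix is the target genetic-correlation matrix
inflated by the mixture factor `(q_p + q_r/t)/q_p` (so the blend of
pleiotropic and single-trait QTLs hits the target in expectation; an
unattainable combination raises).  Remaining QTLs affect a single trait;
optional sign flips on non-primary traits create negative pleiotropy.
Effects are then rescaled **per trait** so realized additive variances
equal the targets exactly — a diagonal rescale, preserving the sparsity
structure (a full Cholesky transform would make every QTL pleiotropic).
Realized genetic correlations approach the target at O(1/√n_qtl); ±0.1 at
200 QTLs in the tests.

Phenotypes normalize total (genetic + residual) variance to 1 per trait:
`σ_a² = h²`, `Σ_e` has diagonal `1 − h²` and configurable residual
correlations (default 0).  Design effects (replicate, block within
replicate, normal with configurable SDs) are added on top; ramets share
the breeding value and differ in residual and placement.  Genotype
missingness is uniform at random.  Realized truth (breeding values,
empirical Σ_a, Σ_e, per-trait h²) is recorded for recovery tests.

What the generator does not emulate: linkage and LD decay, selection over
generations, dominance/epistasis, genotyping error, non-normal residuals,
spatial field trends.

## Reference problem sizes

The packaged verification experiments (tests and the acceptance script)
use sizes chosen to make Monte-Carlo answers stable while keeping a full
run at desk scale:

* parameter-recovery grid: 600 individuals (60 full-sib families of 9 plus
  60 founders), 2,000 markers, 200 QTLs, two traits, h² ∈ {0.1, 0.3, 0.5}
  × r_G ∈ {0, 0.45, 0.9}, chains 20,000/5,000/10;
* selection-vs-benchmark experiment: 400 individuals (40 full-sib
  families of 9 plus 40 founders), 1,500 markers (filtered at MAF 0.05),
  50 QTLs, three traits with h² = (0.1, 0.4, 0.4) where trait 1 correlates
  with trait 2 at r_G = 0.4 (low/moderate regime) or 0.9 (strong regime),
  3-fold cross-validation, chains 2,500/800/5 per fold, 10 replicates per
  regime.  In this simulated world the only channel by which selection can
  change accuracy is QTL tagging through the weighted kernel — a channel
  that grows *stronger* with the shared genetic signal — so gains pattern
  with strong, not weak, genetic correlation; real populations carry LD
  and diversity structure this generator deliberately omits, and results
  on them can differ in direction (see the generator caveats above).

## Known limitations

* `G_w` variance components are scale-shifted relative to VanRaden `G`
  (see above); use the rescale flag when comparing variance components
  across kernels.
* The univariate observation-level sampler requires balanced replication;
  the documented workaround (pre-correction to genotype level) matches the
  two-stage analysis flow the package is built around.
* With an identity kernel and a single record per individual, σ_g² and
  σ_e² are not separately identifiable and the h² posterior reflects the
  prior; heritability statements require either a structured kernel or
  replication.
* Bayesian credible intervals for h² are bounded at 0 and are not
  numerically comparable to REML confidence intervals that can cross 0.
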