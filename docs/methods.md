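# Methods

## The one-step genomic prediction model

Phenotypes from a gridded, non-replicated field trial are modelled jointly
with genome-wide markers in a single linear mixed model:

    y = X tau + Z u + Zg (a + p) + e

* `tau` — fixed effects: an intercept, optionally centred linear row and
  column trends (off by default; enable with `fixed_trend=True` when a
  trial shows a global gradient).
* `u ~ N(0, sigma2_u I)` — extraneous design effects (blocks), included
  only when the layout carries block identifiers.
* `a ~ N(0, sigma2_a K)` — additive genetic effects through the genomic
  relationship matrix `K = M M' / s`, where `M` is the lines x markers
  matrix of homozygote codes and `s = trace(M M') / n` forces
  `trace(K) = n`.  The scaling makes `sigma2_a` and `sigma2_p` comparable.
* `p ~ N(0, sigma2_p I)` — residual (non-additive) genetic effects.
* `e ~ N(0, sigma2 R)` with `R = AR1(rho_r) x AR1(rho_c)` — separable
  first-order autoregressive plot errors over the trial grid, the standard
  spatial model for row/column trend in plant breeding trials.

Genotype codes are `{-1, +1}` for the two homozygote classes and `0` for
heterozygotes; the panels this package targets come from inbred
line-breeding programs, so heterozygotes are rare and the cross-product
diagonal is essentially the marker count.  No column centering is applied:
`K` is the bare scaled cross-product.  Missing calls are mean-imputed per
marker before the kinship build; markers with minor allele frequency
strictly below 0.01 are removed (a marker at exactly 0.01 is kept).

### REML estimation

Variance parameters maximise the residual log-likelihood

    l_R = -1/2 [ log|H| + log|X' H^-1 X| + y' P y ],    H = var(y),

reported up to the usual additive constant.  The search runs L-BFGS-B over
log-variances (so positivity is structural) and the raw autocorrelations
bounded to (-0.98, 0.98), with a Nelder-Mead polish when the quasi-Newton
line search stalls at the numeric-gradient noise floor.  Variances are
floored at `1e-8 x var(y)` (scaled by the mean genetic diagonal for the
additive component, which keeps the reduced-rank marker model on the same
footing); estimates landing at the floor are reported as pinned.
Convergence comes from the optimiser's own criteria (relative function
tolerance 1e-11); non-convergence is flagged on the result, never silent.
Each likelihood evaluation builds `H` densely and Cholesky-factorises it;
the AR1 x AR1 correlation is evaluated directly from row/column distances
of the observed plots, so masked plots and ragged grid edges need no
padding.  Dense evaluation is exact and, at the panel sizes this package
targets (up to a few thousand plots), faster to the optimum than exploiting
the Kronecker structure would make it.

GBLUPs of the additive effects are `a_hat = sigma2_a K Zg' P y`.  `Zg' P y`
is kept on the fitted model: it is the sufficient statistic for both GBLUP
extraction and direct marker-effect estimation.

### Training models and marker effects

Cross-validation masks validation plot records (NaN) and refits with the
non-genetic parameters (`sigma2`, `sigma2_u`, `rho_r`, `rho_c`) frozen at
their full-model estimates; only the genetic variances are re-estimated.
"Non-genetic" follows the genetic/non-genetic partition of the model: the
genetic components are exactly those attached to `Zg`.

Marker effects come from one of two routes, switched on the marker:line
ratio (threshold 0.9, configurable):

* **Back-solve** (markers >= 0.9 x training lines):
  `q = M_t' K_t^-1 a_t`.  As written this carries the scale constant:
  `M_t q = s a_t` exactly for full-rank `K_t`.  Validation predictions
  `M_v q` are therefore `s` times the conventional back-solve; every
  downstream accuracy is a Pearson correlation, which cannot see the
  scale, so the literal form is kept and documented rather than
  re-normalised.  A singular training kinship gets an optional ridge of
  `1e-6 x mean(diag)`.
* **Direct reduced-rank fit** (markers below the threshold): the genetic
  term is reformulated as `g = M* q + p`, `q ~ N(0, sigma2_a I)`, which
  replaces the rank-deficient `K` with the raw Gram matrix `M* M*'`.
  Effects are `q = sigma2_a M*' Zg' P y`.  With the same data the two
  routes are the same model up to `sigma2_a(direct) = sigma2_a(backsolve)/s`;
  the acceptance suite verifies their validation predictions correlate
  above 0.999.

### Accuracy

Prediction accuracy is the Pearson correlation between validation-set
genomic predictions and the additive GBLUPs those lines receive in the
full-data model — a *relative* accuracy measuring how well a reduced
training set recovers the maximal model's ranking, not accuracy against
ground truth.  (On synthetic data the generator's true breeding values are
also available and used in unit tests.)  Spearman is available as an
option.  Check lines (the repeated grid checks) are genotyped panel members
kept in every training set and never validated: their replicated plots
anchor the spatial calibration.

## Cross-validation designs

* **Size series** — lines shuffle into five folds (two at desk scale);
  each fold's complementary pool is carved into `floor(pool/size)` disjoint
  subsets per target size, all predicting that fold; the full pool is the
  maximal point.
* **Cluster designs** — K-means (k = 5) on the rows of the simple-mismatch
  dissimilarity matrix, 25 restarts, seeded.  Equal per-cluster samples
  are partitioned and rotated in aligned chunks: all-clusters
  (train/valid quotas split equally over clusters), within-cluster,
  between-cluster narrow (every ordered cluster pair), between-cluster
  broad (train split equally over the k-1 non-validated clusters, all
  rotations).  Totals follow the 2:1 train:validation ratio of the
  panel-scale design (1,000/500; 80/30 or 160/50 at desk scale).
* **Cohort designs** — for d prior cohorts (d = 1, 2, 3), training takes
  `cohort_size / d` lines from each of the d years preceding the
  validation year, rotated without replacement; validation is a full
  cohort-sized sample of the following year.

Equal allocation is used wherever the design fixes only totals, and all
aligned rotations of disjoint partitions are enumerated (cap
configurable).  Every split records its derived seed through the design's
master seed.

## Marker-density thinning

Reduced panels are chosen for even genome coverage and high MAF: the map is
cut into contiguous equal-cM bins — bins allocated to chromosomes by
largest-remainder apportionment of map length, one bin per target marker —
and each bin contributes its highest-MAF marker (ties broken by marker id).
Empty bins are backfilled from the globally highest-MAF unselected markers,
so the subset size is exact.  Summaries report unique map positions,
markers per position (2 decimals), the mean interval *total map length /
unique positions* (100 positions on a ~3,120 cM map give 31.2 cM), and
mean MAF across the whole panel.  The density series ends with the full post-filter panel as a
map-free entry.  The MAF filter is applied before map restriction.

## The synthetic breeding program

The generator produces the structural regime the analysis assumes, not any
particular real panel:

* **Populations.** Ancestral allele frequencies uniform on (0.05, 0.95)
  with a configurable fraction (default 10%) drawn near fixation so the
  realised MAF spectrum reaches the 0.01 filter bound.  Frequencies drift
  through a two-level Balding-Nichols hierarchy: two germplasm pools at
  `F = divergence x split`, then populations within pools at the remaining
  drift.  Clusters are therefore *unevenly* related, as breeding programs
  are — this matters for the between-cluster designs, where a broad
  training set always contains a relative of the held-out cluster.
* **Families.** Each cohort is a set of crosses: families get their own
  Balding-Nichols perturbation of the cohort frequencies (default
  `F = 0.6`, 10 families per cohort), and fully inbred lines are drawn
  within families.  Family blocks give within-cluster kinship its real
  strength; without them, within-cluster prediction degenerates to
  cluster-mean sharing.
* **Cohorts and selection.** Successive cohorts are near-siblings of a
  slowly shifting parent pool: the frequency response to truncation
  selection (top 20% on the designated trait's true breeding values) is
  evaluated on a large virtual sample (n = 1,000) of the pool.  Wheat
  cohorts a year apart come from overlapping crossing pools with long
  generation intervals, not from each other; modelling them as a tight
  parent-child chain makes recency-relatedness cancel the diversity
  benefit of older cohorts.  Cohort means of the selected trait rise
  monotonically and its QTL frequencies shift beyond neutral drift.
* **Traits.** Four defaults spanning architectures: 2 QTL (major-gene,
  h2 = 0.85), 6 QTL (oligogenic, 0.70), 150 QTL (quantitative, 0.60),
  800 QTL (polygenic, 0.35).  Effects are Gaussian; true breeding values
  are exact QTL sums.  QTL of the selected trait are drawn before cohort
  generation; other traits draw theirs afterwards from markers that
  actually segregate (panel MAF >= 0.05), so a 2-QTL trait cannot lose all
  variation to drift.
* **Trial.** A 24-range grid grown to fit the panel, one plot per line,
  one check per 11 plots cycling through three designated check lines,
  randomised plot order.  Plot errors are an exact AR1 x AR1 Gaussian
  field (`rho_r = rho_c = 0.5` by default); residual (and optional block)
  variance is scaled per trait so the realised heritability among test
  plots hits the trait's target.

**What the generator does not emulate:** linkage disequilibrium and
haplotype structure (markers are independent given family frequencies),
meiosis and pedigrees, epistasis, genotype-by-environment interaction.
Passing tests therefore demonstrate the pipeline's statistical machinery
and the relatedness/diversity phenomena, not LD-driven effects such as
marker-density plateaus at real-data densities.

## Reproduction studies and problem sizes

The studies in `gsdesign/studies.py` (run by `scripts/acceptance.py` and
the acceptance tests) use desk-scale conditions chosen to finish in minutes
on one CPU while preserving each phenomenon's structural regime:

* design arithmetic at the full 10,375-line scale (pure combinatorics);
* density-table worked examples on a reconstructed 21-chromosome map with
  stacked positions (10,000 markers / 4,590 positions and 13,639 / 4,593);
* route equivalence on a 300-line, 1,000-marker trial;
* parameter recovery: 50 trials of 400 lines at
  `(sigma2_a, sigma2_p, sigma2, rho_r, rho_c) = (1, 0.25, 0.5, 0.5, 0.5)`
  on the checked layout — the repeated checks are what separate `sigma2_p`
  from `sigma2` when most lines have a single plot; plus a dense
  grid-search oracle on a 24-observation instance;
* cluster ordering: three replicate 650-line, 600-marker panels at
  divergence 0.3, training 80 / validation 30;
* size response: sizes 30-240 plus the full ~325-line pool, two folds;
* density interaction: three replicate 1,350-line, 1,500-marker panels at
  divergence 0.5, training 160, densities 150 vs full;
* cohort benefit: two replicate 800-line panels with four selected
  cohorts, 180-line cohort samples, polygenic (selected) vs major-gene
  (neutral) trait.

The qualitative orderings are properties of design means; individual
replicates are noisy (validation sets of 30-50 lines within single
clusters), which is why the structure studies aggregate over replicate
panels.

## Numerical choices and degenerate inputs

* Variance floor `1e-8 x var(y)` (per-component reference scale); rho
  bounds +/-0.98; ridge `1e-6 x mean(diag)` for singular training kinship.
* MAF boundary strict (`< 0.01` removed); MAF ties in bin selection broken
  lexicographically by marker id.
* K-means: 25 restarts, labels 1..k, deterministic under seed; the elbow
  scan seeds each k separately.
* PCA: column (marker) mean-centred, unscaled.
* Degenerate inputs: all-identical genotype panels warn of rank-one
  kinship; an all-zero marker matrix, empty post-filter marker set,
  duplicate ids, grid overflows and marker-set mismatches raise.
* A masked fit requires at least three observed plots; phenotypes with
  zero variance are rejected.

## Known limitations

* No LD: density phenomena are driven by kinship-estimation noise and QTL
  tagging rather than haplotype tagging, so absolute density plateaus do
  not transfer to real arrays.
* The spatial likelihood is dense (O(n^3) per evaluation); panels beyond
  ~5,000 plots would want the Kronecker factorisation this implementation
  deliberately avoids.
* The reduced-rank route assumes homoscedastic marker effects
  (`q ~ N(0, sigma2_a I)`); no BayesA/B-style heteroscedasticity.
* Single environment by design; no GxE.
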