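# Methods

This note documents the models, estimators and numerical choices behind
the package, the design of the synthetic study, and what the test suite
does and does not establish.

## Affinity statistics

All statistics operate on per-population alt-allele frequencies with
complete-case SNP exclusion per statistic.

**Hudson Fst** uses the ratio-of-averages estimator with per-population
small-sample correction (allele counts `n1`, `n2`):

    num = (p1 − p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    den = p1(1−p2) + p2(1−p1)
    Fst = Σ num / Σ den

Ratio of averages (not average of ratios) keeps low-information SNPs
from dominating.  For two populations independently diverged by drift F
from a common ancestor the estimand is exactly F (tested against a
Balding–Nichols-style simulation).

**Outgroup f3(X, Y; O)** is the mean over SNPs of
`(pO−pX)(pO−pY) − pO(1−pO)/(nO−1)`; the correction removes the
outgroup's finite-sample variance, making the estimator unbiased for
the population-level covariance.  The bias term is applied to the
outgroup only; **f4(A, B; C, D)** is the uncorrected mean of
`(pA−pB)(pC−pD)`.  With A an outgroup and B a test population, f4 < 0
means the test population shares more alleles with C.

**Block jackknife.** SNPs are partitioned into contiguous blocks within
chromosomes (default density about one block per 200 SNPs, matching the
~692 blocks per ~139k SNPs used for genome-scale data).  Standard
errors use the weighted delete-one-block jackknife of Busing et
al. (1999) with block SNP counts as weights; for equal blocks this is
the textbook delete-one jackknife, and identical leave-one-out
estimates short-circuit to SE = 0 exactly.

**Inbreeding (fhat2).** Per sample, `F = (O − E)/(L − E)` with O the
observed homozygote count, L the non-missing SNP count and E the
HWE-expected homozygote count `Σ[1 − 2p(1−p)·2n/(2n−1)]` using pooled
full-sample frequencies.

**Genotype filters.** MAF filtering pools all samples; LD pruning is
greedy within sliding windows of 50 variants stepping by 10 (the
variant-count reading of the PLINK `--indep-pairwise 50 10 0.3` flags):
while any surviving pair in the window exceeds r² = 0.3
(pairwise-complete Pearson; pairs with < 3 complete observations count
as r² = 0), the later SNP of the worst pair is removed and never
reconsidered.

## Friction grids and least-cost distances

A friction grid assigns each cell a traversal cost; impassable cells
carry `+inf`, never a large finite number.  Land costs `TRI + 1`, where
TRI is the mean absolute elevation difference to the up-to-8 valid
neighbors (edge cells use the neighbors they have; nodata propagates).
Feature classes are independently `omit` / `barrier` / `costed`
(riverside-in-desert has no barrier mode):

* glacier, desert, swamp costed → `max(TRI + 1) + 1`, the ceiling being
  evaluated over passable land of the current grid (no external
  reference region exists);
* river and riverside-in-desert costed → `TRI + 1` (note this equals
  the base land cost, so a costed river only differs from an omitted
  one when it interacts with other layers);
* straits (Bosporus-Dardanelles, English Channel) costed → cost-1
  corridors through otherwise impassable sea.

Overlap precedence is barriers > riverside-in-desert > costed surfaces
> base.  Sea (non-land) is impassable by default — only opened strait
corridors cross it.

Least-cost distances are single-source shortest paths (Dijkstra via
`scipy.sparse.csgraph`) on the 8-connected lattice with edge weight
`(cost_i + cost_j)/2 · cell_size · (√2 for diagonals)` — the common GIS
accumulated-cost convention, symmetric by construction.  Populations
snap to the nearest passable cell by Euclidean cell distance (ties
row-major, default radius 10 cells).  The matrix is explicitly
symmetrized (averaging transposed entries) to remove float accumulation
order effects; grids up to 4×4 are verified against exhaustive
simple-path enumeration.

## The Gamma spline surface

Affinity is modeled as `f3 ~ s(LCD, BP)` with a Gamma likelihood and
log link.  The smooth is a thin-plate-type radial basis
(`η(r) = r² log r`) over the standardized predictors, with knots chosen
by deterministic k-means (seeded), the polynomial-orthogonality
constraint absorbed by a QR reparameterization (making the wiggliness
penalty positive semidefinite), and an optional second shrinkage
penalty on the planar terms so that a featureless response collapses to
the intercept alone (edf → 1).  Fitting is penalized IRLS — for the
log-link Gamma the working weights are identically 1, so the penalized
normal matrix is factorized once per smoothing parameter.  Smoothing
parameters minimize a REML-type score of the Gaussian working model
(profiled scale, log-determinant terms over the penalized subspace),
optimized by a coarse grid plus Nelder–Mead; GCV is the flagged
fallback.  Reported quantities: edf = trace of the influence matrix,
Gamma deviance explained, adjusted R² on the response scale, and the
log-scale intercept.  On noisy Gamma data the fit agrees closely with
mgcv's `gam(y ~ s(x1, x2, k=30), family=Gamma(log), method="REML")`
(deviance explained matching to ~3 decimal places in development
checks).

Rows with non-positive f3 are dropped (and counted) when the affinity
table is built: outgroup-f3 is positive in practice and the Gamma
family requires a positive response.

## Cross-validated model selection

Each candidate friction model yields an LCD matrix, an affinity table
and a k-fold (default ten-fold) cross-validated MSE on the response
scale.  Folds are stratified by modern population, because the rows
sharing a modern population are statistically dependent; when a
population has fewer rows than folds, plain shuffled folds are used
(logged).  With the small tables of the synthetic study the MSE of a
single fold partition is noisy, so the selector averages several seeded
partitions (`repeats`, default 3) — still ten-fold CV, just stabilized.
Ranking is ascending MSE with ties broken toward fewer included feature
classes.

## Validation statistics

* **Correlations:** Pearson r(f3, LCD) and r(f3, BP); the semi-partial
  correlation is operationalized as the correlation between LCD and the
  residuals of the linear regression of f3 on BP (the controlled
  variable is stated in the contract, the estimator was an open
  choice).  Windowed variants restrict to a mean-BP range.
* **Kappa:** rows with |Z| > 3 enter a 2×2 table of sign(f4) against
  sign(LCD.D); Cohen's kappa is computed from the counts, and the
  p-value permutes the LCD.D margin — with fixed margins this is
  exactly hypergeometric resampling of the agreement cell, which is
  vectorized (default 10⁵ draws, seeded, one-sided greater).
  Degenerate tables with chance agreement 1 define kappa as 1 when
  agreement is perfect and 0 otherwise.
* **Mantel tests:** Pearson correlation of upper-triangle entries with
  joint row/column permutation of the second matrix, one-sided
  "greater" by default (isolation by resistance predicts a positive
  association); `p = (1 + #{r* ≥ r}) / (1 + n_perm)`.  The partial
  variant residualizes both upper-triangle vectors on the control
  matrix's and permutes the residual vector; a matrix collinear with
  the control returns a partial r of exactly 0.
* **Ancestry contribution distance:** per modern population, the vector
  of median f3 to each ancient geographic grouping; matrix entries are
  L1 (Manhattan) distances between vectors.

## The synthetic study

The generator defines the conditions under which the pipeline is
exercised and validated.

**Landscape.** A 40×40 grid of 50 km cells.  Elevation is the cube of
smoothed (σ = 2 cells) standardized Gaussian noise, scaled by 1.5: the
cubing concentrates ruggedness into ridge-like structures, so the cost
ceiling (max ≈ 10) stands well above the median cell cost (≈ 2.7), as
in real mountain landscapes where a few ranges dominate.  Feature masks
are quantile thresholds of independent smoothed fields with a longer
correlation length (σ = 4 cells), giving a few large contiguous
blobs — glaciers 18%, deserts 22%, swamps 12%, rivers 8% of cells —
rather than scattered speckle.  Landscapes regenerate (≤ 10 tries)
until ≥ 90% of land is one 8-connected component.

**Populations.** 5 modern + 6 ancient + 1 outgroup site, spread by
greedy farthest-point sampling over the largest land component.
Ancient ages sit on 2 kyr intervals between 6 and 30 kyr BP; geographic
groups follow grid quadrants.

**Genotypes.** Per SNP, `p0 ~ U(0.1, 0.9)`; population frequencies are
`p0` plus multivariate-normal drift with covariance
`p0(1−p0) · s · exp(−βd·LCD − βt·|Δt|/1000)` (nearest-PSD repair by
eigenvalue clipping when needed), truncated to [0, 1]; the outgroup
drifts independently.  Defaults: `s = 0.10`, outgroup scale 0.10,
`βd = 3.2e-4` per cost-km (median pairwise decay ≈ 0.35), `βt = 0.02`
per kyr, 5000 SNPs on 10 chromosomes, 10 diploid samples per
population, 5% missingness.  These values give pairwise Fst of
0.02–0.10 and outgroup-f3 contrasts well resolved at 5000 SNPs — the
magnitudes seen between human populations at this time depth.  The
truncation biases the closed-form expectation by a few percent, so the
self-consistency test compares estimates against the exact expectation
of the truncated law obtained by independent Monte Carlo.

**What the simulation does not emulate:** linkage disequilibrium within
blocks (SNPs are independent draws), ascertainment bias of SNP panels,
reference-panel pseudo-haploidy and damage patterns of ancient DNA,
admixture events, and real allele-frequency spectra.  Passing tests
therefore show that the estimators and the selection machinery behave
correctly under the isolation-by-resistance model, not that the model
fits any particular empirical dataset.

**Recovery experiment design.** The candidate set contains the true
permeable model (all surface features costed), the three "keep only one
surface" variants and a ruggedness-only baseline.  Two constraints
shaped this set: a costed river is cost-identical to plain land, so
river-only contrasts are vacuous; and with a high cost ceiling a
barrier variant of a costed class is nearly observationally equivalent
(both force detours), making such contrasts unidentifiable at desk
scale.  Candidates therefore differ by omission of the large surcharged
surfaces, which reroutes least-cost paths decisively.  Model selection
uses basis dimension 8 and 4 CV repeats.

## Numerical choices and degenerate inputs

* Impassable cells are `inf`; unreachable pairs stay `inf` and their
  affinity rows are dropped (logged).
* IRLS caps the linear predictor at ±30 and declares non-convergence
  after 100 iterations.
* The REML score floors the penalized RSS at 1e-12 (constant-response
  fits are otherwise log(0)).
* `make_blocks` apportions blocks to chromosomes by largest remainder
  (≥ 1 per chromosome) and splits within chromosomes to sizes differing
  by at most one SNP.
* Jackknife blocks with zero weight are excluded (logged); fewer than
  two usable blocks is an error.
* Haploid male X genotypes are expected on the {0, 2} diploid scale;
  the X is otherwise treated like an autosome.
* Text-matrix genotype dialect: whitespace-separated, `NA` missing,
  header of SNP ids, first column the sample id, optional `.map`
  companion (chromosome, id, position).

## Known limitations

* The Fst estimator is a published frequency-based analogue of the
  EIGENSOFT smartpca computation, not a re-implementation of it; exact
  numerical agreement with smartpca is out of scope.
* The REML criterion operates on the Gaussian working model (a PQL-type
  approximation), not the exact Gamma restricted likelihood; mgcv's
  Laplace-based criterion can select slightly different smoothing
  parameters on small noisy tables.
* Connectivity of candidate grids is not guaranteed: a barrier-heavy
  model may evaluate on fewer affinity rows than its competitors, which
  is inherent to comparing models by CV on their own reachable pairs.
* The 8-connectivity/√2 convention is one of several accumulated-cost
  conventions in GIS tools; LCDs from 4-connected or spread-style
  algorithms will differ by small factors.
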