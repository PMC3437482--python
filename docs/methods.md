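# Methods

`spatialqg` estimates quantitative-genetic variance components in the
presence of fine-scale shared spatial effects. This note documents the
models, the numerical choices, and what the synthetic-data tests do and
do not demonstrate.

## The problem

In a wild, philopatric population, relatives live near each other. Any
environmental effect that varies over space therefore generates
phenotypic resemblance among kin, and an animal model that knows only
the pedigree will book that resemblance as additive genetic variance.
The package provides two covariance structures that let the mixed model
see space directly, so that genetic and spatial similarity compete to
explain the data:

* a **home-range overlap matrix S**, with entries in [0, 1] on the same
  scale as relatedness, fitted exactly like the A matrix; and
* a **separable AR1×AR1 lattice process** over 100-m grid cells of the
  individuals' average lifetime locations.

## Pedigree and the A matrix

The additive relationship matrix is built by the tabular method in a
canonical parents-first order: `a_ii = 1 + 0.5 a(dam_i, sire_i)` and
`a_ij = 0.5 (a(j, dam_i) + a(j, sire_i))`, with unknown parents
contributing zero. Parents never listed as individuals become implicit
founders (assumed non-inbred and unrelated); unknown-parent sentinels
("", "0", "NA") are configurable. The diagonal uses the inbreeding
adjustment of the standard recursion throughout; for pedigrees with many
unknown parents this treats all founders as unrelated, which is the
usual (and only available) assumption. Matrices are stored dense, which
is comfortable to a few thousand individuals, and exchanged on disk as
lower-triangle triplet text with an id sidecar.

Validation is by Monte-Carlo gene dropping: two distinguishable founder
alleles per individual are transmitted down the pedigree and relatedness
is estimated as twice the identity-by-descent probability of random
allele pairs. The tabular matrix must agree with this estimate within
its Monte-Carlo error (exactly, where transmission is deterministic).

## Home ranges and the S matrix

Census locations are recorded to the nearest 100 m, so coincident fixes
are broken by adding uniform noise on [-20, 20] m to each coordinate
before kernel estimation. Utilization distributions (UDs) use a
bivariate product-normal kernel with the reference bandwidth
`h = sigma_pooled n^(-1/6)`, `sigma_pooled = sqrt((var x + var y)/2)`;
a fixed bandwidth can be supplied instead. Cell masses are exact normal
integrals over each cell (per-axis CDF differences), not midpoint
evaluations, so the only discretization error is grid truncation. Groups
with fewer than 10 fixes are excluded, each with a logged record.

Defaults that the source analyses leave open, chosen here once:

| parameter | default | rationale |
| --- | --- | --- |
| grid cell | 10 m (20 m in the simulation pipeline) | closed-form checks pass within 2% at this resolution |
| extent pad | 3 bandwidths | keeps truncated mass negligible |
| isopleth for "core range" | 0.95 | conventional kernel home-range level |
| jitter | on for both sizes and overlap | consistent treatment of all KDE inputs |

Home-range size at isopleth q is the area of the highest-density cells
whose cumulative mass first reaches q (greedy accumulation, stable
ties), in hectares. Overlap is Bhattacharyya's affinity
`BA = sum sqrt(m1 m2)`; grids snapped to a common lattice reduce to
aligned cell sums (and the whole S matrix to a Gram product of
square-root mass vectors, hence positive semidefinite by construction);
unaligned grids are conservatively resampled onto the union bounding box
at the finer cell size with separable area-weighted mass reassignment.
Overlap uses lifetime fixes pooled across years; sizes are per
season-year. Individuals without ranges keep identity rows in S. An
optional eigenvalue clip (`psd="clip"`, epsilon 1e-8) restores
invertibility when duplicate UDs make S singular; the flag and the
largest entry change are recorded.

## The lattice and AR1×AR1 covariance

Mean lifetime locations map to integer (row, col) cells of a 100-m grid
anchored at a south-westerly origin. The spatial covariance between
occupied cells is `variance * phi_row^|dr| * phi_col^|dc|` — the
occupied-cell principal submatrix of the Kronecker product of two AR1
correlation matrices, hence positive definite for |phi| < 1. Effects are
indexed by cell: individuals sharing a cell share one spatial effect
(the alternative, one effect per individual with duplicated rows, gives
an equivalent marginal covariance up to the cell-sharing structure and
costs more parameters' worth of matrix size). Single-axis (column-only
or row-only) processes are the same machinery with the other phi fixed
at 0. The phi search interval defaults to [0, 0.999] and can be widened
to (-0.999, 0.999); estimates within 1e-3 of an interval end are
reported as bound, mirroring the printed-table convention for
components bound at 0 or 1.

## REML engine

The model is `y = Xb + sum_k Z_k u_k + e` with `u_k ~ N(0, s2_k G_k)`
and the restricted log-likelihood
`l_R = -1/2 [log|V| + log|X'V^-1X| + y'Py + (n-p) log 2 pi]`.
Numerical choices:

* The response is standardized internally; variances are optimized on a
  log scale (bounded at 1e-10 of the response variance, which is the
  zero boundary for reporting purposes), phis on their natural bounded
  scale.
* L-BFGS-B with analytic gradients for the linear variance parameters
  (`d l/d s2_k` via the REML projection identities) and central
  differences for phis; three seeded starts by default (equal-split
  plus log-normal jitters), followed by a projected Newton polish on the
  coordinates away from their bounds. On balanced designs this lands on
  the closed-form ANOVA estimators to ~1e-9.
* Standard errors come from the numerically differentiated Hessian of
  the restricted likelihood at the optimum in natural parameters;
  parameters at a boundary are excluded (their SE is reported as 0).
  Proportions and h2 use the delta method on that covariance.
* A variance at its lower bound is reported as exactly 0 with a bound
  flag. Duplicate identity terms on the same levels trigger a
  non-identifiability warning; only their sum is estimable.
* Likelihood-ratio tests use the naive chi-square df equal to the
  difference in (co)variance parameter counts (1 for the S matrix, 2 for
  a single-axis SAC, 3 for row+column). Because a null variance sits on
  the boundary, the naive test is conservative; the 50:50 mixture
  correction is deliberately not applied, so reported p-values are upper
  bounds. AIC is `-2 l_R + 2 (variance-parameter count)` and is refused
  across fits with different fixed effects or data.
* Missing data are dropped listwise per model with a logged count.
* The Sum-V credibility guard flags a fit whose total variance departs
  more than 3-fold (configurable) from the baseline model's — the
  symptom of a poorly estimated spatial process, which in practice
  accompanies autocorrelation estimates bound at 1.

## Synthetic data

The generator emulates the study-system structure without claiming
demographic realism: discrete generations; every non-founder's mother
known; sires drawn from an external pool with a configurable unknown
fraction (default 0.3); founder females settle uniformly on a
3 km x 3 km rectangle; daughters settle at their mother's range center
plus isotropic Gaussian dispersal (default sd 100 m, well below the
study extent, so matrilines cluster); fixes are Gaussian scatter
(sd 150 m) about the center, ~20 per season, rounded to the 100-m census
grid. Phenotypes are assembled from the same mixed-model components the
fitter estimates — `y = mu + a + pe + m + u_year + s + e` with
`a ~ N(0, V_A A)` and `s ~ N(0, V_S S)` (or an AR1×AR1 field), drawn by
matrix square roots. Founder females receive private maternal levels so
their records survive listwise deletion. The default variance mix
(V_A = 0.3, V_S = 0.5, V_E = 0.2 over ~300 phenotyped females, four
generations) is the recovery scenario used by the acceptance tests;
named presets (`rhr`, `shr`, `bw`, `lbs`) carry illustrative mixes for
repeated- and single-measure traits. Everything is deterministic given
the config seed, with independent streams per stage.

What the generator does **not** emulate: overlapping generations,
survival and density dependence, male space use, temporal drift in
ranges, non-Gaussian space use, or measurement error structured in time.
Passing tests therefore demonstrate correctness of the estimation
machinery under the stated generative model and the qualitative
genes-vs-space confounding mechanism; they do not certify field
estimates for any real population.

## What the tests show

* Exactness: A matrix vs gene dropping; AR1×AR1 vs explicit Kronecker;
  grid BA and isopleth areas vs Gaussian closed forms; REML vs balanced
  ANOVA estimators; the reported likelihood vs an independent dense
  evaluation and local-optimality under perturbation.
* Calibration: with data simulated from the model, replicate-mean
  estimates of every component match the truth within familywise
  Monte-Carlo error (100 replicates); the boundary LRT rejects below its
  nominal level under the null (500 replicates).
* The headline mechanism: when relatives share space and half the
  variance is spatial, the naive animal model roughly triples the true
  heritability (replicate means ~85-87% vs a truth of 30%), while the
  S-matrix model recovers it; the naive estimate exceeds the S-matrix
  estimate in every replicate. This reproduces the direction, and an
  order of magnitude comparable to, the published contrast the package
  is designed to probe — on synthetic data only.

Problem sizes in the test suite and acceptance script (pedigrees of up
to ~660, 100 and 500 replicate batches, 20 gene-drop pedigrees at 1e5
drops) were chosen so the full pipeline demonstrates its properties at
desk scale on one CPU.

## Known limitations

* Simultaneous SAC + S-matrix fitting is possible through the API but
  untested against any reference and not part of the default variants.
* Dense linear algebra bounds practical model sizes to a few thousand
  observations; no sparse/average-information shortcuts are implemented.
* The AR1×AR1 process is indexed by occupied cell; very uneven cell
  occupancy makes the spatial variance parameter scale-dependent in the
  usual way for lattice models.
* Delta-method SEs for proportions are first-order; for components near
  a boundary they understate uncertainty.
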