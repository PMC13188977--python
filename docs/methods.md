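# Methods

## The testing problem

Many high-dimensional datasets — microbiome profiles above all — are
analysed through a matrix of pairwise dissimilarities `Φ` with entries
`ϕ_ij = ϕ(Y_i, Y_j)` (Euclidean, Bray-Curtis, Jaccard, ...).  Given a
grouping of the `n` samples into `G` groups, the *dispersion* of group
`g` is carried by the multiset of its within-group dissimilarities

    Φ_g = { ϕ_ij : g_i = g_j = g, i < j },   |Φ_g| = n_g (n_g − 1) / 2.

Classical dispersion tests (PERMDISP/betadisper; mean-within-distance
permutation tests) summarize `Φ_g` by a single number — mean distance
to a centroid, or mean squared pairwise distance — and so cannot see
groups that match in mean spread but differ in the *shape* of their
distance distribution (heavier tails, bimodality, outliers).  The test
implemented here (DTH, distance-based test of homogeneity) compares the
whole distributions: its null hypothesis is

    H0 : L_1 = ... = L_G,

where `L_g` is the distribution of within-group dissimilarities in
group `g`.

## The DTH procedure

For each group the mean empirical CDF of within-group distances is

    F̄_g(z) = (2 / (n_g (n_g − 1))) · #{ (i < j) in g : ϕ_ij ≤ z },

equivalently the average over group members of the per-sample CDFs
`F_ig(z)`.  For each pair of groups two discrepancy statistics are
computed exactly on the merged step functions:

* `K = sup_z |F̄_1(z) − F̄_2(z)|` (Kolmogorov–Smirnov), powerful against
  location–scale differences of the distance distribution;
* `W = ∫ |F̄_1(z) − F̄_2(z)| dz` (1-Wasserstein), powerful against tail
  and outlier differences.

Within-group distances are mutually dependent (each sample enters
`n_g − 1` of them), so the classical asymptotic nulls for `K` and `W`
do not apply.  Instead `R` null replicates are generated (see
*Permutation schemes*), giving `K_r`, `W_r` for `r = 1..R` per pair.
P-values follow the `+1` permutation convention
`p0K = (1 + #{K_r > K_0})/(R + 1)`, and each replicate also receives a
rank-based p-value `prK = rank(−K_r)/R` against the other replicates
(denominator `R`: each replicate is compared to the remaining ones;
ties get the maximum rank, the conservative choice).  The two tests are
combined through the omnibus statistic `m_r = 1 − min(pK_r, pW_r)`,
computed for `r = 0` (observed) and every replicate.  For `G = 2` the
final p-value is `(1 + #{m_r > m_0})/(R + 1)`.  For `G > 2` the
pairwise omnibus p-values are combined with Fisher's statistic
`f_r = −Σ_{g<g'} ln p_r^m(g, g')` and the final p-value is
`(1 + #{f_r > f_0})/(R + 1)`.  All pairs and both statistics reuse one
shared replicate stream, exactly as a single `r`-loop.

The dedicated `G = 2` path and the Fisher path coincide whenever the
final p-value is below 1, because `−ln(1 − m)` is strictly increasing
in `m`: with `c = #{m_r > m_0} < R` exceedances, exactly the same `c`
replicates satisfy `prm < p0m`, ties included.  Only the boundary
`c = R` escapes, where the rank denominator `R` and the permutation
denominator `R + 1` put the weakest replicate on opposite sides.  The
equality is asserted on seeded data in the test suite.

Strict inequalities are used in every counting formula.  A fully
degenerate matrix (all distances equal) yields all-zero statistics; the
test then returns `p = 1` with a warning rather than the formula value,
which would misread "no ordering information" as strong evidence.

A continuous covariate is handled by quantile-discretizing it into
`bins` groups (default 3 — a balance between resolution and the
`n_g ≥ 2` requirement; exposed as a flag) with ties assigned to the
lower bin, then testing the resulting groups.

## Permutation schemes

Two replicate generators produce within-group distance sets with
homogeneous dispersion while preserving the original cardinalities:

* `labels` (default): uniformly permute the group labels and re-extract
  within-group sets from the fixed distance matrix.  This preserves the
  dependence structure among distances and is *exact* under
  exchangeability — which holds in every null scenario of the
  simulation benchmark, where group locations are identical.
* `pooled`: pool the observed within-group multisets and randomly
  re-partition them into sets of the original sizes.  Between-group
  distances are never touched, making this a location-robust option for
  real data with suspected centroid shifts.

Per-replicate RNG substreams are spawned deterministically from the
master seed, so results are bit-identical regardless of execution
order, and identical seeds give identical p-values end to end.

## Comparator tests

* **betadisper-style** (PERMDISP): principal-coordinates embedding of
  the Gower-centered matrix `−½ J (Φ∘Φ) J`; axes split by eigenvalue
  sign; each sample's squared centroid distance is (squared distance on
  positive axes) − (squared distance on negative axes), clamped at zero
  before the square root — the standard heuristic correction for
  non-Euclidean dissimilarities.  The statistic is the one-way ANOVA F
  directly on the centroid distances (the form used by the permutation
  test, rather than Levene's absolute-deviation variant), with label
  permutations recomputing centroids and F.  The observed F agrees with
  R's `vegan::betadisper(type = "centroid")` to ~1e-12 on both
  Euclidean and Bray-Curtis fixtures (asserted in the test suite).
* **GO.perm-style**: per-group dispersion `V̂_g = mean over Φ_g of
  ϕ²/2` — the U-statistic form of the variance; for Euclidean distance
  the two-point case reproduces the sample variance, and any positive
  rescaling cancels in the permutation p-value.  The statistic is the
  size-weighted between-group sum of squares `Σ_g n_g (V̂_g − V̄)²`,
  with p-values from the shared replicate engine.  This is a
  reimplementation anchored to the published description of the method
  (mean of all within-group pairwise distances); the original's
  asymptotic-null variant and spatial-median centering are out of
  scope.

## Simulation benchmark

**Normal scale mixtures** (`simulate_normal`): `Y_i | v_i ~ N_d(0, v_i
I_d)` with the dispersion `v_i` drawn per sample from a group-specific
mixing distribution.  Scenarios: S0 `v ~ Gamma(α_g, κ_g)` with `κ_g =
(Γ(2α_g + ½)/Γ(2α_g))^{-2}`, which makes `E[√(v_i + v_j)] = 1` and
hence equal expected within-group Euclidean distances across groups
(this exponent is fixed by the derivation and verified by a Monte-Carlo
test); S1 log-normal with `μ_g + σ_g²/2 = 3/2`, constant mean
dispersion `E(v) = e^{3/2}` but varying shape; S2 log-normal with
common `μ` and varying `σ_g²` (mean dispersion varies); S3 fixed `v_g`
per group.  Parameter tables are defined for `G ∈ {2, 3, 5}`; in the
`G = 5` rows groups 3 and 5 deviate while 1, 2, 4 stay at the null
value, and in the `G = 3` rows the middle group takes the half-strength
deviation — the evident pattern of the parameter families.  Defaults:
`d = 500`, `n = 150` split evenly, `θ ∈ {0, 0.5, …, 2}`; Euclidean
distance.

**Negative-binomial counts** (`simulate_negbin`): `d = 500` taxa,
`Y_ij ~ NB` with success probability `p = r_i/(μ + r_i)` so that
`E(Y|r) = μ`, `Var(Y|r) = μ + μ²/r`, and per-sample size parameter
`r_i ~ InvGamma(α_g, β_g)` (`E(1/r) = α_g/β_g`, hence `Var(Y) = μ +
μ²·α_g/β_g` unconditionally) or fixed per group in S3.  S1 sets
`β_g = α_g` so mean overdispersion is constant while its distribution
varies; S2 varies `β_g` at fixed `α = 3`; `θ ∈ {0, 0.5, …, 3}`;
Bray-Curtis distance.  The NB mean is not pinned down by the benchmark
description; the package uses `μ = 10` for every taxon, group and
scenario — constant so that only dispersion separates groups — exposed
as `mu_mean`.

Every scenario collapses to identical group distributions at `θ = 0`,
so samples are exchangeable and label-permutation tests are exactly
valid there: empirical size is a legitimate calibration surface.  All
simulators are seeded and deterministic.

What the generators do *not* emulate: the sparsity, taxon-specific
means, compositional correlation structure and zero-inflation of real
microbiome count tables (real data have unequal per-taxon abundances;
here every taxon shares one mean).  Passing size/power checks on these
grids therefore validates the test machinery and its calibration under
exchangeability, not robustness to every feature of real sequencing
data.

`simulate_continuous` provides a generic covariate-dispersion design
(`x ~ U(0,1)`, `Y ~ N_d(0, e^{slope·x} I_d)`) for exercising the
discretization front end.

## Study sizes and numerical choices

* The shipped calibration runs (acceptance script and test suite) use
  200 simulated datasets per grid cell with `R = 199` permutations —
  sizes chosen so the binomial Monte-Carlo error of a grid-averaged
  rejection rate (~0.004 at 2400 draws) is well below the differences
  that matter at `α = 0.05`.  The study driver accepts any
  `n_reps`/`R`; the CLI default is `R = 999` (p-value resolution
  0.001).
* `K`/`W` are evaluated by a stable argsort of the pooled values with
  signed ECDF weights; within a block of tied pooled values only the
  block-end running sum is an ECDF evaluation, so ties are handled
  exactly.  Agreement with `scipy.stats.ks_2samp` /
  `wasserstein_distance` and with a brute-force step-integral oracle is
  asserted to 1e-12.
* PCoA drops eigenvalues with `|λ| < 1e-10 · max|λ|`; distance-matrix
  input is symmetrized when asymmetry ≤ 1e-8 (error above), diagonal
  tolerance 1e-12.
* Floats are serialized with 17 significant digits; file round trips
  are exact (readers use round-trip float parsing).

## Known limitations

* The replicate-generation schemes are this package's own surrogates
  for a null-replicate construction defined in external work; `labels`
  is exact under exchangeability, `pooled` is offered for
  location-shifted data, but neither claims to reproduce any external
  package's scheme.
* Power (not size) depends on the unspecified NB mean `μ`; results at
  other `μ` require rerunning the study with the `mu_mean` flag.
* Unbalanced designs are supported by the API (arbitrary
  `group_sizes`) but no calibrated reference values ship for them.
* UniFrac and other phylogeny-aware dissimilarities, rarefaction, and
  analytic (non-permutation) p-values are out of scope.
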