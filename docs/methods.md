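# Methods

This note documents the models, formulas and numerical choices behind
`scnkit`, and what the synthetic-cohort tests do and do not establish
about real data.

## Synthetic cohort generator

### Generative model

Parcels are placed on a sphere of radius r = 100 mm (the scale of the
fsaverage sphere) by a Fibonacci golden-angle lattice, one lattice per
hemisphere with the right hemisphere mirrored (x → −x). The lattice is
deterministic and quasi-uniform, so nearest-neighbour spacings are
nearly constant and cluster centroids cannot degenerate.

The dependence structure is hierarchical:

* Hemisphere parcels are partitioned into **planted contiguous clusters**
  of ~3 parcels (consecutive spiral indices are spatial neighbours).
  This mirrors the empirical finding that parcels reduce to compact
  clusters of 2–5 neighbours (mean 2.9 at 180 parcels / 62 clusters).
* A **Gaussian Markov random field over the latent clusters** carries
  the between-region structure. Its precision is `I − (S + F)` where
  both components have random-sign entries with magnitudes
  `exp(−decay · d)` of the geodesic distance between cluster centroids:
  a steep short-range component S (decay 0.04/mm, range ≈ 25 mm) and a
  slow near-uniform component F (decay 0.002/mm) modelling the weak
  long-range covariance floor. Each component is rescaled to a fixed
  spectral radius (defaults 0.15 and 0.5).
* Each parcel is its cluster latent plus independent within-cluster
  noise (SD 0.3 in latent units); each hemisphere adds independent
  mirror noise (SD 0.3). Values are affinely mapped to positive areas
  (mean 500 mm², scale 60 mm²/unit, floored at 1 mm²), so cluster sums
  are approximately normal by construction.
* **Group effect:** the affected group's latent precision off-diagonals
  are multiplied by `group_scale`; values above 1 scale all partial
  correlations up, producing larger correlation variance, shorter
  weighted paths and lower Jensen–Shannon complexity — the signature of
  a globally stronger-covariance population. `group_scale = 1` gives an
  exact null (identical generating model), used for calibration runs.
* **Site effects:** per-site, per-parcel additive shifts
  (SD `site_shift`, default 20 mm²) and multiplicative scalings of the
  deviation from the nominal mean (log-SD `site_scale`, default 0.05),
  shared between groups — exactly the location-scale family ComBat
  models.

### Why spectral normalisation, and why these strengths

Positive definiteness caps how strong partial correlations can be: for
any K-vertex precision with unit diagonal and off-diagonal spectral
radius below 1, the Frobenius mass of the partial-correlation matrix is
bounded, which for K = 62 limits the achievable SD of the 1891 true
partial correlations to ≈ 0.1. Normalising each component to a fixed
spectral radius keeps the control model comfortably inside this bound
(radius ≈ 0.65 combined) so that scaling by 1.5 (≈ 0.98) remains
positive definite **without diagonal loading**. This matters because the
loading safety net (add λI until the minimum eigenvalue exceeds a 0.01
margin) rescales all partial correlations down, and would otherwise
silently cancel the group effect whenever the affected matrix needed
more loading than the control one. Loading is therefore retained only as
a guard for user-supplied extreme configurations.

### Study conditions and cohort sizes

Generator defaults follow the reference design: 102 subjects per group,
360 parcels, two sites. For the end-to-end group-difference recovery
runs the package uses 400 subjects per group instead: the sampling noise
of a 62-variable partial-correlation estimate is ≈ 1/√(n−K) per edge
(≈ 0.16 at n = 102), which swamps the strongest group effect any
positive-definite synthetic model can encode, whereas real cortical
covariance is far stronger than the generator's. The larger cohort
restores a comparable signal-to-noise regime; the directions it tests
(variance ratio, path length, complexity) are size-invariant. The
remaining caveat is inherent: passing synthetic recovery shows the
pipeline propagates a known effect faithfully, not that effects of this
size are detectable in 102-subject MRI samples.

The end-to-end null-calibration suite uses many small replicate cohorts
(60 subjects per group, 30 hemisphere parcels) because calibration needs
replicates, not size.

## Atlas reduction

Ward agglomerative clustering operates on the rows of the parcel-level
partial-correlation matrix under Euclidean distance — each parcel's row
is its covariance fingerprint, and Ward requires Euclidean geometry.
Cluster-count selection computes, for each candidate K: mean silhouette
and Dunn index (same row-vector distances; an all-singleton partition is
rejected as degenerate rather than scored zero, and an infinite Dunn
ratio is capped at 1e12), the ARI between separate left- and
right-hemisphere clusterings, and the mean ARI of subject-subsample
clusterings against the full-sample labeling (cheaper than all pairwise
subsample comparisons and carrying the same consistency signal). The
four metrics are min-max normalised across the K range — the simplest
way to make them commensurate — summed, and the argmax taken, with ties
broken toward smaller K for parsimony; the modal K over repeated seeded
runs is reported. Only the subsampling varies between seeds.

## Network construction

Covariance uses the unbiased (n−1) estimator; partial correlations are
invariant to the divisor. Inversion requires n_subjects > n_clusters and
fails loudly otherwise — regularized precision estimation (graphical
lasso, Ledoit–Wolf) is deliberately out of scope because dimensionality
is reduced by clustering instead, which preserves empirical
relationships. Sign-restricted subnetworks zero the excluded edges but
keep the full vertex set so metrics stay comparable across modes.

ComBat is the standard parametric empirical-Bayes location-scale model:
per-feature site means and variances estimated on standardized
residuals, shrunk across features under normal / inverse-gamma priors
(method-of-moments hyperparameters, fixed-point iteration to 1e-8), then
removed; age, sex and group are protected covariates. Output matches
Bioconductor `sva::ComBat` to that package's own solver tolerance. A
consequence of shrinkage worth knowing: with few features, per-feature
batch estimates are pulled toward the cross-feature mean, so only the
shared component of a site offset is fully removed.

Distribution checks follow the Gaussian-model diagnostics: per-cluster
Anderson–Darling normality (estimated-parameter variant) and
between-group variance F-tests on cluster areas (BH-FDR within the
family), and on the n(n−1)/2 vectorized upper-triangle correlations:
Shapiro–Wilk normality, Welch t-test of means (sign bias) and a
two-sided variance-ratio F-test (magnitude shift), oriented
control/affected so F < 1 means stronger affected correlations.

## Global metrics

All metrics evaluate the printed formulas exactly, on symmetric
non-negative weights with zero diagonal:

* **Clustering** C = Tr A³ / Σ_{i≠j}[A²]ᵢⱼ. Note this ratio is
  homogeneous of degree 1 in the weights (C(cA) = cC(A)); on a complete
  graph with uniform weight w it equals w.
* **Path length / efficiency** use edge lengths 1/wᵢⱼ (weights are
  associations, not costs) and Dijkstra shortest paths; L averages dᵢⱼ
  over ordered pairs and raises on disconnected graphs with a component
  report; E averages 1/dᵢⱼ with unreachable pairs contributing zero, so
  it is defined for empty graphs. Because SCNs are dense, shortest paths
  may legitimately hop through intermediate vertices whenever
  1/w_ik + 1/w_kj < 1/w_ij; no weight thresholds are applied.
* **Betweenness** uses Brandes accumulation with equal-length ties
  counted into the path counts at an absolute tolerance of 1e-12 on path
  lengths, and normalises by the (N−1)(N−2)/2 unordered pairs excluding
  the vertex, so a star hub scores exactly 1.
* **Jensen–Shannon complexity**: vertex profiles pᵢ(j) = wᵢⱼ/Σₖwᵢₖ
  (uniform 1/n fallback for isolated vertices, e.g. in sign-restricted
  subnetworks), pairwise JSD in bits via the mixture entropy identity,
  JSDᵢ the row mean including the zero self term, and JSD_global the
  1/n² double-sum mean — identical to the 2/n² upper-triangle form by
  symmetry, which the tests assert to 1e-12. Because profiles exclude
  the self-weight, JSD_global is not zero on finite complete graphs; it
  vanishes only when profiles coincide (e.g. the uniform fallback).

## Spatial analysis

Geodesics use d = r·atan2(‖Pᵢ×Pⱼ‖, Pᵢ·Pⱼ) after projecting centroids
radially onto the sphere (the formula presumes on-sphere points;
centroids of compact clusters sit just inside it). Centroids whose norm
deviates from r by more than 25% are flagged — the programmatic stand-in
for a visual sanity check on cluster compactness.

Small-world propensity reconfigures the observed weights into a lattice
null (weights sorted descending assigned to edge slots sorted by
distance ascending, ties broken by index for determinism) and an
ensemble of 10 random shuffles (seeded). ΔC = (C_latt−C_obs)/(C_latt−C_rand)
and ΔL = (L_obs−L_rand)/(L_latt−L_rand) are clamped to [0,1] (degenerate
null spreads are flagged and clamped to the boundary);
φ = 1−√((ΔC²+ΔL²)/2), α = atan2(ΔL, ΔC), δ = 4α/π−1. The lattice null
has *higher* clustering and *higher* weighted path length than the
random average on distance-decaying networks — the orientation the ΔL
denominator presumes. Observed and null metrics share the inverse-weight
path convention. φ and δ are invariant to uniform weight rescaling.

The distance–weight model is a Gaussian penalized-spline GAM: response =
upper-triangle edge weights of both groups, design = intercept + group
indicator + one cubic B-spline smooth of geodesic distance per group
(basis dimension k = 5, quantile-interior knots, second-difference
penalty, sum-to-zero constraint absorbed by a null-space
reparametrisation). Smoothing parameters minimise GCV (Nelder–Mead on
log λ from three starts); standard errors use the Bayesian posterior
covariance σ̂²(XᵀX+Σλ S)⁻¹. The group term is tested by t with n−edf
degrees of freedom, smooths by a Wald F, and group-specific smooth
shape by analysis of deviance against a reduced shared-smooth model
(χ² on the edf difference). Predictions and SEs are evaluated at 100
equidistant points spanning the observed distance range; the pointwise
group comparison uses z = (p̂ₐ−p̂_b)/√(SEₐ²+SE_b²) with
Benjamini–Hochberg correction over the 100 tests. Against R's mgcv
(per-group `s(d, by=g, k=5)`) the group coefficient agrees to ~1e-7 and
grid predictions correlate above 0.997; residual differences reflect the
basis family (B-splines here, thin-plate there), mostly at the range
boundaries.

## Inference

* **Matching**: within sex strata, the assignment problem minimising
  total absolute age difference is solved exactly with the Hungarian
  algorithm — optimal 1:1 matching on one covariate is an assignment
  problem, so no propensity model is involved. No control is reused.
* **Permutation tests on global metrics** swap subject rows of the
  cluster-aggregated area tables (post-harmonization) and rebuild each
  group's network and metric inside every iteration. The one-sided p is
  the plain proportion of null differences at least as extreme in the
  chosen direction; the (b+1)/(m+1) correction is available behind a
  flag (used by the calibration tests, where exact uniformity matters).
  Effect size = observed difference / null SD. Failed iterations (e.g.
  a singular resample) are excluded and counted.
* **Distribution comparisons** (e.g. betweenness vectors): mean,
  variance, skewness and kurtosis differences under pooled-resplit
  permutation; the Pearson-correlation statistic permutes the vertex
  alignment of one vector instead, since label swaps within vertex pairs
  leave a symmetric correlation unchanged.
* **Jackknife** SE: √(((n−1)/n)·Σ(θ₍ᵢ₎−θ̄)²) over leave-one-subject-out
  recomputations; equals s/√n exactly for the sample mean.
* **Power**: the minimum detectable d solves the noncentral-t power
  equation (via statsmodels); the permutation power simulation draws
  unit-normal samples a distance d apart and applies a two-sided inner
  permutation test of the mean difference. The two agree (two-sided
  power at n = 102, d = 0.4 is ≈ 0.81), and the simulation returns
  α when d = 0.

## Problem sizes used by the test suite

Unit tests run on 6–40-vertex networks and 60–120-parcel cohorts; the
end-to-end recovery run uses the full 360-parcel / 62-cluster geometry
with 400 subjects per group, 300 permutation iterations and a 5-network
random-null ensemble; null calibration uses 60 replicate cohorts at 99
permutations with the add-one p-value correction; the permutation power
simulation uses 2000 outer replicates × 500 inner permutations.

## Known limitations

* The generator emulates the statistical shape of parcellated surface
  area, not anatomy: no cortical folding, no realistic parcel geometry,
  no empirical area distributions (none are published for the reference
  datasets), Gaussian tails only.
* Planted clusters are index-contiguous blocks on the Fibonacci spiral —
  compact, but not shaped like cortical areas; clustering-recovery
  results speak to the algorithm, not to atlas biology.
* The group effect is a uniform scaling of latent couplings. Real
  conditions likely perturb specific systems; pointwise distance
  resolution is demonstrated with injected mid-range bumps in the unit
  tests, not in the end-to-end run.
* Population-level Jensen–Shannon complexity is nearly invariant to
  uniform coupling scaling (profiles renormalise); the JSD group
  difference the pipeline detects is a signal-to-noise interaction and
  correspondingly small — as it is in real data, where reported effect
  sizes are ≈ 0.5 SD.
* Anderson–Darling p-values use the estimated-parameter normal variant;
  with very large cohorts trivial deviations from normality will reject.
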