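# scnkit

Structural covariance network (SCN) analysis of parcellated cortical
surface area.

An SCN is a graph whose vertices are cortical regions and whose edge
weights are correlations of a morphometric measure — here absolute
surface area in mm² — across subjects. Because regional surface areas
co-vary under shared neurodevelopmental influences, the global topology
of these networks (clustering, path length, efficiency, complexity,
small-worldness) summarises how coordinated cortical growth is in a
population, and how that coordination differs between groups such as
clinical cohorts and matched controls.

`scnkit` implements the full analysis chain for researchers working with
subject × parcel surface-area tables (e.g. from the 360-region HCP
multimodal atlas):

1. **Atlas reduction.** With n subjects below the parcel count, the
   covariance matrix is rank deficient, so parcels are reduced to
   clusters by Ward hierarchical clustering of the parcel-level partial
   correlation matrix, with the cluster count selected by a composite of
   silhouette, Dunn index, and adjusted-Rand consistency across
   hemispheres and subject subsamples.
2. **Network construction.** Per group, cluster areas Σ are inverted to
   the precision matrix Ω and partial correlations
   ρ̃ᵢⱼ = −Ωᵢⱼ/√(Ωᵢᵢ Ωⱼⱼ) define signed edges; |ρ̃ᵢⱼ| are edge
   weights (positive-only and negative-only subnetworks optional).
   Scan-site batch effects are removed beforehand with parametric
   empirical-Bayes ComBat, protecting age, sex and group.
3. **Global metrics.** Weighted clustering C = Tr A³ / Σ_{i≠j}[A²]ᵢⱼ,
   characteristic path length L and global efficiency E on inverse-weight
   shortest paths, betweenness centrality, and a network complexity
   index: the mean Jensen–Shannon divergence (bits) between the
   normalised edge-weight distributions of all vertex pairs.
4. **Spatial analysis.** Great-circle geodesics between cluster
   centroids on the spherical cortical surface; small-world propensity φ
   and continuum position δ against a distance-ordered lattice null and
   weight-shuffled random nulls; penalized-spline GAMs of edge weight
   versus geodesic distance with per-group smooths, a parametric group
   term, and pointwise FDR-corrected Z-tests along the distance axis.
5. **Inference.** 1:1 optimal (Hungarian) age/sex matching of controls,
   permutation tests that swap group labels at the level of the
   surface-area data and rebuild networks inside each iteration,
   null-SD-normalised effect sizes, jackknife standard errors, and the
   design power analyses (noncentral-t solution and a permutation power
   simulation).

Restricted MRI datasets cannot ship with the package, so a first-class
synthetic cohort generator (`scnkit.synthetic`) reproduces the
statistical structure the analysis assumes — spatially contiguous parcel
clusters, partial correlations centred on zero with magnitudes decaying
over geodesic distance, group effects that scale correlation magnitude,
and site batch effects — making every stage testable end to end.

## Worked example

Run the whole pipeline on a synthetic cohort in which the affected
group's latent couplings are scaled by 1.5 (400 subjects per group, 360
parcels reduced to 62 clusters, 650-subject control pool for the
clustering, 300 permutations):

```python
import scnkit as sk

cfg = sk.RunConfig(
    outdir="scn_run", seed=1,
    synthetic={"n_subjects_per_group": 400, "n_parcels": 360,
               "group_scale": 1.5},
    n_cluster_pool=650, K=62, n_perm=300, swp_n_random=5)
results = sk.run_pipeline(cfg)
```

On this cohort the run prints (see `scn_run/results.json`):

```
var_F = 0.863  (p = 0.0014)      # control/affected variance ratio of the
                                 # 1891 partial correlations: affected
                                 # correlations have larger magnitudes
L     = 15.24 (control) -> 13.95 (affected)   # shorter weighted paths
C     = 0.0537 -> 0.0580                      # more triangle weight
JSD   = 0.2107 -> 0.2090                      # lower network complexity
perm  L: observed -1.290, effect -3.08, p = 0.000
SWP   phi 0.338 / 0.329, delta -0.970 / -0.973  # random-like topology
GAM   group coefficient 0.0047 (p = 0.0026), 14 FDR-significant
      distance points
```

This is the qualitative signature of a globally *stronger-covariance*
group: larger correlation variance (F < 1), reduced path length, higher
clustering, reduced Jensen–Shannon complexity, and elevated edge weights
across the geodesic-distance range. Setting `group_scale: 1.0` gives a
null cohort on which all group-difference p-values are calibrated.

The same stages are available from the shell:

```bash
scnkit all --config config.yaml        # full pipeline
scnkit generate --config config.yaml   # synthetic cohort only
scnkit cluster --areas areas.tsv --k 62 --out labels.csv
scnkit build-scn --areas areas.tsv --phenotypes pheno.csv \
    --labels labels.csv --group control --out pcorr_control.csv
scnkit metrics --pcorr pcorr_control.csv
```

Exit codes: 0 success, 2 configuration error, 3 data error, 4 numerical
failure.

## Documentation

`docs/methods.md` describes the generative model behind the synthetic
cohorts, every formula and numerical choice in the metric and inference
code, and the known limitations of what synthetic-data tests can show
about real MRI data.
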