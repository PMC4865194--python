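# Methods

`betascape` implements a complete inference chain for the spatial
structure of beta diversity — the variation in species composition
among sites — on a planar grid of cells. The chain is the "raw-data"
approach: the response is the site-by-species incidence matrix itself,
transformed and modelled directly, rather than a pairwise dissimilarity
matrix. This note records the models, the parameters that matter, the
numerical choices, and the known limits of what the synthetic
experiments demonstrate.

## Pipeline overview

1. **Range estimation.** Each species' occurrence points are
   triangulated (Delaunay); the mean length of the unique triangulation
   edges is computed; every triangle with an edge longer than that mean
   is discarded; the union of surviving triangles is the range polygon.
   This mean-edge rule keeps ranges compact where the convex hull would
   bridge gaps much wider than the typical point spacing.
2. **Rasterization and matrix assembly.** A grid cell is occupied when
   its centre falls inside (or on the boundary of) the range polygon;
   cells above an elevation cap (default 100 m) are removed first, one
   unit may be down-sampled to a fixed cell count, and cells left with
   no species are dropped (the Hellinger transform is undefined on zero
   rows).
3. **Transforms.** The 0/1 matrix is Hellinger-transformed
   (y'ᵢⱼ = √(yᵢⱼ/rowsumᵢ), rows acquire unit norm, making Euclidean
   ordination appropriate for composition data) and then linearly
   detrended on the centred geographic coordinates, so the finer-scale
   spatial model is not asked to reproduce a planar gradient.
4. **Predictors.** Climate variables are pruned of collinearity
   (greedy, |Pearson r| > 0.85) and summarised by correlation-matrix
   PCA (2 axes by default) into the **Clim** set; the categorical unit
   label is dummy-coded (k−1 indicators) into the **Geo** set; Moran
   Eigenvector Maps supply the **Broad** and **Fine** spatial sets.
5. **MEM engine.** Candidate neighbourhood distances span the longest
   minimum-spanning-tree edge (smallest distance keeping the graph
   connected) to the maximum pairwise distance, 50 candidates by
   default. For each candidate, the binary distance-band adjacency W is
   doubly centred (Ω = C W C, C = I − 11ᵀ/n) and eigendecomposed;
   eigenvectors with positive eigenvalues model positive spatial
   autocorrelation (Moran's I of eigenvector k equals
   (n/1ᵀW1)·λₖ, asserted to 1e-10 on every basis). The candidate is
   scored by AICc over nested models of its eigenvectors ordered by
   explained sum of squares, pooling residual sums of squares across
   species (single-dispersion approximation). MEMs enter the model by
   forward selection under the double stopping criterion: stop when the
   best candidate's permutation p-value exceeds α = 0.05 or when the
   cumulative adjusted R² passes the global model's adjusted R². The
   selected vectors are split into broad and fine submodels (by
   eigenvalue rank, sign-run period, or an explicit judgment-encoded
   list) and any MEM with |r| > 0.3 against a Geo dummy is removed, so
   the spatial sets do not silently re-encode the unit layout.
6. **Variation partitioning.** The adjusted R² (Ezekiel:
   1 − (1−R²)(n−1)/(n−m−1), with m the *rank* of the predictor block)
   of every non-empty union of the four sets is computed by RDA
   (least-squares projection of the centred response on the centred
   predictors). The 2⁴−1 = 15 disjoint fractions are obtained by
   solving the exact linear system that relates union-R² values to
   fractions, so the fractions sum to the full-model adjusted R² by
   construction (asserted to 1e-12). Negative fractions are an honest
   property of the adjustment and are reported (the plotting helper
   hides them, as partition diagrams conventionally do). Unique
   fractions and the full model are tested by permutation pseudo-F:
   free row permutation for simple RDA, reduced-model residual
   permutation under covariables.
7. **Neutrality diagnostic.** The component of the (transformed)
   matrix explained by the spatial sets (Broad ∪ Fine) is extracted;
   per-species Moran's I correlograms are computed over
   equal-pair-count distance classes (Sturges' rule on the pair count
   by default); **M** is the matrix of pairwise Manhattan distances
   between correlograms over the classes valid for all species, **R**
   the matrix of pairwise Pearson correlations between species
   profiles. Under neutral dynamics — independent species with similar
   autocorrelation — M and R are unrelated; shared drivers push the
   relationship negative (species with similar correlograms also
   covary). The Mantel correlation of the two lower triangles is tested
   by simultaneous row/column permutation (exhaustive for ≤ 7 species),
   one-tailed for positive association by default, so a strongly
   negative statistic yields p near 1, evidencing non-neutral structure.

## Synthetic metacommunities

The generator emulates a coastal-lowland study design: an nx × ny
lattice of 5-km cells (≈25 km² each), partitioned along the x-axis into
contiguous equal blocks playing the role of geomorphological units;
climate variables as unit-variance Gaussian random fields with
isotropic exponential covariance (range defaulting to a quarter of the
x-extent) optionally mixed with a per-unit offset
(`climate_block_confounding` c gives climate = (1−c)·field + c·block,
restandardised — a convex mixture so c = 1 is a pure block effect) and
optionally carrying a spatially unstructured "nugget" share
(`climate_nugget`, microclimate); elevation as a shorter-range field
clipped at zero, centred near 60 m so a 100-m cap removes a realistic
minority of cells.

Species follow one of three archetypes:

- **unit_restricted** — Bernoulli presence at `baseline_prevalence`
  inside 1–2 allowed units, zero outside (dispersal-limited,
  historically confined ranges);
- **climate_niche** — presence probability
  logistic(logit(baseline) − Σₖ((climₖ−optₖ)/breadthₖ)²), a Gaussian
  niche whose optimum equals the baseline prevalence and which
  flattens to that constant as breadth → ∞;
- **neutral** — presence by thresholding an exponential-covariance
  Gaussian field (range `autocorr_range_km`) at the normal quantile of
  1 − `occupancy_rate`, giving spatially coherent but
  species-independent occupancy.

Every species draws from its own child seed (spawned from the master
seed), so species are mutually independent under neutrality — the
property the Mantel diagnostic tests — and a species' realisation does
not change when the rest of the pool does.

### Recovery regimes

The regimes used by the recovery experiments (grid 10 × 5, four units,
24 species, reduced permutation counts so one hundred replicates run in
seconds):

- *geomorphology-dominated*: 75% unit_restricted / 15% niche / 10%
  neutral, confounding 0.3 — the Geo-unique fraction is the largest
  unique fraction in ≥95 of 100 replicates;
- *climate-dominated*: 8% / 84% / 8% with confounding 0, niche breadth
  1.2 sd and climate nugget 0.5 — Clim-unique overtakes Geo-unique;
- *all-neutral*: 100% neutral — the Clim-unique fraction is centred on
  zero (|mean| < 0.02 over 50 replicates).

The nugget in the climate regime is essential, not cosmetic: a purely
smooth climate surface is representable by the MEM basis, so once
space is controlled the climate-unique fraction is structurally near
zero no matter how strongly climate drives the community (the same
mechanism that yields small climate-unique fractions in field studies
of this design). Only the spatially unstructured share of climate
identifies Clim uniquely.

## Numerical choices

- Delaunay edge filter: unique undirected edges, inclusive (≤)
  comparison; a `per_triangle` mode (shared edges counted twice) exists
  because the averaging convention is ambiguous in practice.
  Degenerate point sets (< 3 points, collinear, or fully filtered
  triangulations) fall back to discs of radius half the mean edge
  length (global mean when the local one is undefined), so every
  recorded species occupies ≥ 1 cell.
- Cell membership is by centre point only; boundary counts as inside.
- Rank handling: all RDA projections go through an SVD orthonormal
  basis with tolerance 1e-10 relative to the leading singular value;
  adjusted R² uses the effective rank, which is what makes the
  dummy-coded Geo set contribute k−1 (not k) degrees of freedom.
- Permutation p-values are (1 + #{stat* ≥ stat}) / (1 + n_perm); every
  permutation stream takes an explicit seed.
- Forward-selection ties break to the lowest eigenvector index;
  eigenvalue positivity tolerance is 1e-9 × the largest |eigenvalue|.
- Climate-variable pruning keeps the higher-priority member of an
  offending pair; priority is the caller's `keep` list (for bioclimatic
  inputs a sensible list is temperature seasonality, coldest-month
  temperature, precipitation seasonality, driest-quarter
  precipitation), otherwise column order.
- Recommended defaults mirror field practice: correlation-pruning
  threshold 0.85, MEM-vs-Geo pruning threshold 0.3, 50 candidate
  neighbourhoods, α = 0.05, 999 permutations (9999 for the Mantel
  test), 2 climate PCA axes.
- JSON/CSV outputs use 17 significant digits, so a rerun of the same
  config is byte-identical and round-trips lose < 1e-12 per entry.

## What the synthetic experiments do and do not show

The generator produces incidence with known geomorphic, climatic and
neutral components, which validates the *machinery*: oracle-equivalent
statistics, conserved fraction arithmetic, calibrated permutation
tests, and correct qualitative attribution when one process dominates.
It does not emulate several features of real survey data: detection
error and uneven sampling effort, rheophilic or otherwise
habitat-excluded taxa (a curation step left to the caller), realistic
coastline geometry, abundance information (incidence only), or
climate surfaces with the spatial complexity of interpolated station
data. Passing recovery tests therefore supports the inference code,
not any claim that a particular field system is geomorphology-driven.

Known limitations worth keeping in mind when interpreting output:

- Pruning MEMs against Geo (the r > 0.3 rule) protects the historical
  fraction from spatial mimicry but is asymmetric: under purely
  neutral dynamics the unit dummies can absorb residual spatial
  structure, inflating Geo-unique by several points of adjusted R²
  while Clim-unique stays centred on zero. Geo-unique estimates should
  be read with this in mind.
- Hull rasterization smooths within-unit occupancy (absences inside a
  compact range become presences), which shifts variance from the
  unique Geo fraction toward broad-scale spatial and Clim∩Geo shared
  fractions in the full pipeline relative to analyses on the raw
  simulated incidence.
- The broad/fine MEM split is judgment-based in field practice; the
  `explicit` rule exists to encode such judgments, and the default
  eigenvalue split (top half of the selected vectors by eigenvalue
  rank) is a reproducible stand-in, not a canonical definition.
- With four predictor sets the partition has 15 fractions plus a
  residual; three-way and four-way intersections are reported under
  their subset keys (`"Broad&Clim&Geo"`, …) rather than letter labels,
  which are ambiguous in the literature.
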