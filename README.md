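# betascape

Spatial beta-diversity inference for gridded incidence data: from
species occurrence points to a partition of compositional variation
among historical, climatic and purely spatial drivers, with a
diagnostic for neutral dynamics.

## The problem

Community ecologists routinely ask *why* species composition turns
over across a region: is beta diversity driven by contemporary
environmental gradients (climate), by historical/geomorphological
subdivisions that constrained dispersal and colonisation, or by
neutral, dispersal-limited dynamics that generate spatial
autocorrelation without any niche differences? `betascape` implements
the full analysis chain used to separate these drivers on a grid of
sites:

- **Range estimation** from occurrence points by the Delaunay
  mean-edge-length rule (triangles with an edge longer than the mean
  edge are discarded), rasterized to a site × species 0/1 matrix **Y**.
- **Transforms**: Hellinger (y′ᵢⱼ = √(yᵢⱼ/Σⱼyᵢⱼ)) and linear
  detrending on geographic coordinates.
- **Spatial predictors**: distance-based Moran Eigenvector Maps —
  eigenvectors of the doubly centred binary adjacency Ω = C W C,
  keeping positive eigenvalues (positive autocorrelation; Moran's I of
  eigenvector k is (n/1ᵀW1)λₖ). The neighbourhood distance is chosen
  by AICc over 50 candidates spanning the minimum-spanning-tree
  distance to the grid diameter; MEMs enter by forward selection with
  the double stopping criterion (permutation α and the global model's
  adjusted R²), are split into broad/fine submodels, and are pruned of
  vectors collinear with the unit dummies (|r| > 0.3).
- **Variation partitioning** over four predictor sets (Clim, Geo,
  Broad, Fine) by redundancy analysis with Ezekiel-adjusted R²
  (R²adj = 1 − (1−R²)(n−1)/(n−m−1)): all 15 unique and shared
  fractions, summing exactly to the full-model adjusted R², with
  permutation pseudo-F tests of the unique fractions.
- **Neutrality diagnostic**: per-species Moran's I correlograms of the
  spatially predicted matrix, the matrix **M** of Manhattan distances
  between correlograms, the matrix **R** of between-species
  correlations, and a Mantel test of their association — under
  neutrality species are independent with similar correlograms, so M
  and R should be unrelated.

A synthetic metacommunity generator (block-structured landscapes,
autocorrelated climate, unit-restricted / climate-niche / neutral
species archetypes) makes every stage verifiable by parameter
recovery; see `docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate a 16 × 10 lattice (four contiguous geomorphological units, 57
species, 75% of them unit-restricted) and run the whole pipeline:

```python
from betascape.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    simulate=dict(nx=16, ny=10, n_units=4, n_clim=4,
                  climate_block_confounding=0.5, n_species=57,
                  pool=dict(proportions=(0.75, 0.15, 0.10))),
    n_candidates=50, n_perm=999, n_perm_mantel=9999, seed=1,
)
res = run_pipeline(cfg, "out")
vp = res["varpart"]
print(f"cells: {res['community_raw'].n_sites}, species: {res['community_raw'].n_species}")
print(f"best neighbourhood distance: {res['basis'].d_max_km:.1f} km")
print(f"positive-eigenvalue MEMs: {res['basis'].n_vectors}, selected: {len(res['selected'])}")
print(f"full model adjusted R2: {vp.full_model_r2_adj:.3f}")
for name, frac in sorted(vp.unique_fractions().items(), key=lambda kv: -kv[1]):
    print(f"  unique {name}: {frac:.3f} (p = {vp.testable_pvalues[name]:.3f})")
print(f"  shared Clim&Geo: {vp.fraction_table['Clim&Geo']:.3f}")
mres = res["neutrality"][0]
print(f"Mantel r(M, R) = {mres.r:.2f} (p = {mres.p_value:.2f})")
```

prints

```
cells: 125, species: 57
best neighbourhood distance: 10.0 km
positive-eigenvalue MEMs: 44, selected: 38
full model adjusted R2: 0.451
  unique Broad: 0.123 (p = 0.001)
  unique Geo: 0.095 (p = 0.001)
  unique Fine: 0.060 (p = 0.001)
  unique Clim: 0.004 (p = 0.056)
  shared Clim&Geo: 0.174
Mantel r(M, R) = -0.01 (p = 0.71)
```

Reading it: 125 of the 160 cells survive the 100-m elevation mask and
empty-cell drop; the model explains 45% of compositional variation.
The unit structure surfaces twice — as the significant Geo-unique
fraction and, because climate was simulated half-confounded with the
units, as the large Clim∩Geo shared fraction — while the Clim-unique
fraction is near zero, as expected when climate is spatially smooth
and space is controlled. The Mantel statistic near zero says the
spatially structured component is consistent with independent species
(the pool's spatial signal here comes from many independently placed
unit-restricted ranges, not from shared drivers of the spatial
residual).

Each stage is equally usable on its own (`mean_edge_hull`,
`build_matrix`, `hellinger`/`detrend`, `mem_basis`/`forward_select`,
`varpart`, `mantel`, …), and a CLI mirrors the pipeline:

```sh
betascape simulate --nx 16 --ny 10 --seed 1 --out-dir data/
betascape run-all --config config.yaml --out-dir out/
```

Outputs are CSV/JSON with a provenance manifest; rerunning the same
config is byte-identical.

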