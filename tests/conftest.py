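import numpy as np
import pytest

import betascape as b
from betascape.transforms import PredictorSet


@pytest.fixture(scope="session")
def small_landscape():
    return b.simulate_landscape(10, 5, 4, 2, climate_block_confounding=0.3, seed=101)


@pytest.fixture(scope="session")
def small_community(small_landscape):
    pool = b.random_species_pool(20, small_landscape, seed=102)
    cm, occ = b.simulate_community(small_landscape, pool, seed=103)
    return cm, occ


def drop_empty(cm, grid):
    """Remove zero rows/constant columns so transforms are well-posed."""
    occ = cm.values.sum(axis=1) > 0
    nz = cm.values[occ].std(axis=0) > 0
    cm2 = b.CommunityMatrix(cm.cell_ids[occ], cm.species[nz], cm.values[occ][:, nz], "raw")
    return cm2, grid.subset(occ)


def quick_varpart(seed, proportions, confounding=0.3, climate_nugget=0.0,
                  niche_breadth=1.0, n_species=24, n_perm=99, d_max=7.6):
    """Reduced-size end-to-end varpart used by the recovery experiments.

    Runs the complete downstream chain (Hellinger, detrend, MEM basis at
    a fixed connectivity distance, forward selection, broad/fine split,
    pruning vs Geo, four-set partition) on a 10 x 5 lattice.
    """
    land = b.simulate_landscape(10, 5, 4, 2, confounding, seed=seed,
                                climate_nugget=climate_nugget)
    pool = b.random_species_pool(n_species, land, proportions=proportions,
                                 seed=seed + 1, autocorr_range_km=15.0,
                                 niche_breadth=niche_breadth)
    cm, _ = b.simulate_community(land, pool, seed=seed + 2)
    cm2, grid = drop_empty(cm, land.grid)
    cd = b.detrend(b.hellinger(cm2), grid.coords)
    clim, _ = b.climate_pca(land.climate_frame().loc[cm2.cell_ids])
    geo = b.dummy_code(grid.unit)
    basis = b.mem_basis(b.distance_band_weights(grid.coords, d_max))
    sel = b.forward_select(cd, basis, alpha=0.05, n_perm=n_perm, seed=seed + 3)
    broad_set = fine_set = None
    if sel:
        basis = b.classify_scales(basis, sel)
        retained, _ = b.prune_vs_geo(basis, sel, geo)
        broad = [j for j in retained if basis.scale_class[j] == "broad"]
        fine = [j for j in retained if basis.scale_class[j] == "fine"]
        if broad:
            broad_set = PredictorSet("Broad", basis.vectors[:, broad],
                                     [f"MEM{j + 1}" for j in broad])
        if fine:
            fine_set = PredictorSet("Fine", basis.vectors[:, fine],
                                    [f"MEM{j + 1}" for j in fine])
    return b.varpart(cd, {"Clim": clim, "Geo": geo, "Broad": broad_set,
                          "Fine": fine_set}, test_fractions=False)
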