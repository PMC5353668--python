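"""Test for the extinction-debt signal with the three correlation tests.

The debt signal: present-day richness correlates more strongly with *past*
than *present* forest structure. The spatial test adjusts the degrees of
freedom for spatial autocorrelation (effective sample size M̂); semi-partial
and partial tests control the other seven forest predictors.
"""
import numpy as np

import extdebt as ed

world = ed.generate_world(ed.SyntheticConfig(seed=42, resolution=8.0))
grid = world.grid
richness = ed.rasterize_richness(ed.filter_forest_terrestrial(world.species), grid)
dmat = ed.distance_matrix(grid)
mset = ed.compute_metric_set(world.fraction_1500s, world.fraction_2000s, dmat)

ids = grid.land_ids
coords = np.column_stack([grid.centroid_lat[ids], grid.centroid_lon[ids]])
y = richness["mammal"].values[ids]
X = {n: mset.layers[n].values[ids] for n in ed.PREDICTOR_NAMES}

print(f"{'predictor':<10} {'spatial r':>10} {'M-hat':>8} {'p':>9}   "
      f"{'semipart r':>10} {'partial r':>10}")
for name in ed.PREDICTOR_NAMES:
    Z = np.column_stack([X[o] for o in ed.PREDICTOR_NAMES if o != name])
    sp = ed.modified_ttest(X[name], y, coords)
    se = ed.semipartial_correlation(y, X[name], Z)
    pa = ed.partial_correlation(y, X[name], Z)
    print(f"{name:<10} {sp.r:>10.3f} {sp.ess:>8.1f} {sp.p:>9.2e}   "
          f"{se.r:>10.3f} {pa.r:>10.3f}")
# Past-epoch (…1500) spatial correlations exceed their 2000 counterparts:
# the planted extinction debt. M-hat far below the cell count shows how much
# independent information spatial autocorrelation removes.

perm = ed.randomization_test(y, X["Areas1500"], n_permutations=999, seed=1)
print(f"\nrandomization: r(S, Areas1500) = {perm.r_observed:.3f}, "
      f"permutation p = {perm.p:.4f} ({perm.n_permutations} shuffles)")
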