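"""Fit the SAR and map per-cell extinction debt under several z exponents.

Debt(i) = S_obs(i) − S_obs(i)·(A_2000/A_1500)^z. The fitted z comes from
the log-log regression of richness on past forest area; fixed z = 0.25
(conventional), 0.1 and 0.15 (conservative) are mapped alongside it.
"""
import numpy as np

import extdebt as ed

world = ed.generate_world(ed.SyntheticConfig(seed=42, resolution=8.0))
grid = world.grid
richness = ed.rasterize_richness(ed.filter_forest_terrestrial(world.species), grid)
a1500 = grid.layer(world.fraction_1500s.values * grid.cell_areas)
a2000 = grid.layer(world.fraction_2000s.values * grid.cell_areas)

maps, fit = ed.compute_debt_maps(richness["reptile"], a1500, a2000)
print(f"fitted SAR: c = {fit.c:.3f}, z = {fit.z:.4f}, "
      f"R² = {fit.r_squared:.3f} on {fit.n_cells} cells  "
      f"(generative truth: c = 10, z = 0.25)")
for label, dmap in maps.items():
    debt = dmap.debt.land_values
    print(f"  {label:<10} mean debt {np.nanmean(debt):7.2f}  "
          f"max {np.nanmax(debt):7.1f}  credits (debt<0): "
          f"{int(np.nansum(debt < 0))} cells")
# Larger z means a steeper SAR, hence more species committed to extinction
# for the same forest loss; the spatial pattern stays essentially the same.
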