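"""Run the annual dispersal cellular automaton from a point introduction.

Rasterizes two founder populations as 5-km disks (merged into regions at
10 km, as for field-survey records), then simulates 60 years of spread
with the negative-exponential short-distance kernel (lambda = 0.005 / m,
cut at 600 m) plus rare long-distance jumps (probability 0.0005 per
occupied mature cell per year, 600 m - 10 km), constrained by forest
barriers and unsuitable land cover. Prints the percent of suitable
habitat colonized over time, mean and 95% CI across 10 replicates.
"""

import numpy as np

from spreadca import SyntheticSpec, gen_landscape
from spreadca.ca import (
    CellStateGrid, DispersalParams, SuitabilityStack,
    build_initial_distribution, percent_colonized, run_simulation,
)

bundle = gen_landscape(SyntheticSpec(nx=150, ny=150, cell_size=200.0, seed=3,
                                     forest_fraction=0.25, builtup_fraction=0.05,
                                     paddy_fraction=0.08, water_fraction=0.02,
                                     intercept=0.8))
grid = CellStateGrid.from_landcover(bundle.landcover)
good = grid.colonizable() & (bundle.suitability_truth.values >= 0.5)
rows, cols = np.nonzero(good)
X, Y = bundle.landcover.cell_centers()
pts = np.array([[X[rows[0], cols[0]], Y[rows[0], cols[0]]],
                [X[rows[-1], cols[-1]], Y[rows[-1], cols[-1]]]])

init, n_regions = build_initial_distribution(pts, grid, buffer_radius=5000.0,
                                             merge_dist=10_000.0)
print(f"initial distribution: {int(init.values.sum())} cells in {n_regions} region(s)")

stack = SuitabilityStack([(0, bundle.suitability_truth)], invasibility_threshold=0.5)
params = DispersalParams(ldd_freq=0.0005, ldd_max=10_000.0, n_replicates=10)
result = run_simulation(init, stack, bundle.landcover, params,
                        horizon_years=60, master_seed=11)

suit_mask = bundle.suitability_truth.with_values(good.astype(np.int64))
pct = percent_colonized(result, suit_mask)
print("\npercent of suitable habitat colonized (mean [95% CI] over 10 replicates):")
for year in (0, 10, 20, 30, 40, 50, 60):
    row = pct[pct["year"] == year].iloc[0]
    print(f"  year {year:>2}: {row['mean']:5.1f}%  "
          f"[{row['ci_low']:5.1f}, {row['ci_high']:5.1f}]")
print("\nColonization accelerates as long-distance foci seed new expansion")
print("fronts; barrier (forest) and unsuitable cells are never colonized.")
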