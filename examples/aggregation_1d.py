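"""One-dimensional aggregation from 1% noise.

Runs the attractant+repellent model on a 1 cm periodic interval at the
working density 9000 cm^-1 and prints how the density field develops
dense plateaus (near the packing density 28 000) separated by a dilute
background -- the 1D analogue of circular aggregates.
"""

from l1agg.diagnostics import aggregate_summary
from l1agg.scenarios import run_scenario, scenario_preset

sc = scenario_preset("fig3-1d", resolution=512, seed=1, t_end=4e4,
                     snapshot_times=(5e3, 1e4, 2e4))
res = run_scenario(sc)
grid = sc.build_grid()

print("time (s)   plateaus   max rho   10th-pct rho   mass drift")
for t, snap in zip(res.times, res.snapshots):
    import numpy as np
    summ = aggregate_summary(snap.rho, grid, threshold=14000.0)
    p10 = float(np.percentile(snap.rho, 10))
    print(f"{t:8.0f}   {summ.count:8d}   {snap.rho.max():7.0f}   "
          f"{p10:12.1f}   {res.max_mass_drift:.2e}")

print("\nDense plateaus saturate just below rho_max = 28000; the exterior")
print("drops far below the mean: worms have collected into aggregates.")
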