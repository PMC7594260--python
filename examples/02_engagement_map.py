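"""Engagement maps across assumed hemodynamic delays.

Runs the core computation on a small cohort: population masks,
per-voxel preprocessing, neighborhood-averaged delay-shifted controls,
and the drop in network connectivity G(M) - G(M'_x) for every
tight-mask WM voxel, at delays 0/2/4/6 s. The planted mediator lags GM
by 4 s, so its group-mean engagement should peak at the 4 s assumed
delay.
"""

import numpy as np

from wmengage.simulate import generate_cohort
from wmengage.studies import (CLUSTER_CENTER, mean_map, recovery_config,
                              run_cohort_pipeline)

config = recovery_config(seed=42, lag_samples=2, weight=0.9, n_subjects=5)
cohort = generate_cohort(config)
res = run_cohort_pipeline(cohort, delays=(0.0, 2.0, 4.0, 6.0), rescale=False)

print(f"WM voxels evaluated: {res['wm_tight'].n_voxels}, "
      f"subjects: {cohort.n_subjects}")
print("assumed delay ->  mediator engagement | map median (null level)")
for delay in (0.0, 2.0, 4.0, 6.0):
    gmap = mean_map(res["raw_maps"][delay])
    med = float(np.median(gmap.global_values))
    center = gmap.value_at(CLUSTER_CENTER)
    print(f"  {delay:>3g} s      ->  {center:20.3f} | {med:8.4f}")
print("The mediator's connectivity drop is maximal at the assumed delay that")
print("matches its planted 4 s lag; null voxels stay near zero throughout.")
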