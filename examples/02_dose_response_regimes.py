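"""Build a dose-response curve and segment it into expression regimes.

A population of per-cell records is drawn from a piecewise transfer
function (flat below 10^3.5, log-linear rise, flat above 10^5) with 5%
cell-to-cell scatter.  Cells are pooled into equal-count bins by
expression, a ratio-of-variances (RoV) statistic flags the two regime
transitions, and every cell is sorted into no-effect / dose-response /
saturation.
"""

import numpy as np
import pandas as pd

import cytodose as cd
from cytodose.regimes import (assign_regimes, build_drc, detect_thresholds,
                              global_thresholds, rov_series)

rng = np.random.default_rng(0)
n = 4000
expression = 10.0 ** rng.uniform(2, 6, n)
tf = cd.TransferFunction(baseline=100.0, t1=3.5, t2=5.0, plateau=1000.0,
                         noise_cv=0.05)
area = np.array([cd.sample_parameter(tf, e, rng) for e in expression])
records = pd.DataFrame({"total_gfp": expression, "area": area})

curve = build_drc(records, "area", n_min=100, pooling="gmean")
rov = rov_series(curve.stat, N=3)
candidates = detect_thresholds(rov, curve)
g1, g2 = global_thresholds([candidates])
seg = assign_regimes(records, g1, g2)

print(f"{len(curve)} bins of >=100 cells each")
for c in candidates:
    print(f"  {c.direction:>4} transition at expression "
          f"{c.expression:9.0f} (bin {c.index}, |log RoV score| "
          f"{c.magnitude:.2f})")
print(f"global thresholds: G1 = {g1:.0f} (true 10^3.5 = 3162), "
      f"G2 = {g2:.0f} (true 10^5 = 100000)")
print("cells per regime:", seg.counts)
print()
print("An 'up' RoV peak marks where bin-to-bin variability jumps (the "
      "dose-response onset); a 'down' peak marks where it collapses (the "
      "saturation plateau).")
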