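"""Downscale one cell: match a plot, rescale its trees, round the stems.

Shows the algorithm step by step for a single 25 m cell, including the
per-cell weight arithmetic (an enumerated tree on a 400 m2 plot carries
1.5625 stems per cell) and the exact basal-area attainment.
"""

import numpy as np

from virtualforest import FieldPlot, StandSummary, TreeRecord, generate_cell, tree_basal_area
from virtualforest.downscale import cell_rng, cell_weight

print("one tree on 400 m2 -> weight", 10000 / 400, "per ha ->",
      cell_weight(10000 / 400), "per 25 m cell")

plot = FieldPlot(
    "p1",
    trees=[
        TreeRecord("Fa.sy.", 22.0, 90.0, broadleaf=True),
        TreeRecord("Fa.sy.", 34.0, 40.0, broadleaf=True),
        TreeRecord("Pi.ab.", 28.0, 70.0, broadleaf=False),
    ],
)
cell = StandSummary(ba=27.0, dg=33.0, ba_b=0.45)  # lidar-predicted triple
asg = generate_cell(0, cell, plot, cell_rng(seed=1, cell_id=0))
print(f"\nmatched plot {asg.plot_id}, diameter correction alpha = {asg.alpha:.3f}")
for t in asg.trees:
    print(f"  {t.species}: n = {t.n}, dbh = {t.dbh:.1f} cm")
gen_ba = sum(16 * t.n * tree_basal_area(t.dbh) for t in asg.trees)
print(f"generated BA = {gen_ba:.3f} + lost {asg.lost_ba:.3f} "
      f"= {gen_ba + asg.lost_ba:.3f} m2/ha (target {cell.ba})")
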