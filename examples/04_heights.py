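"""Predict tree heights with the published diameter-height parameter sets.

The curve passes through breast height (1.3 m) at dbh -> 0 and saturates
at a species asymptote scaled by the stand development stage (Dg).
"""

import pandas as pd

from virtualforest import assign_heights, load_published_params, predict_height

params = load_published_params("bauges")
print("Beech heights at Dg = 30 cm (Bauges parameters):")
for dbh in (5, 15, 30, 60, 120):
    h = predict_height(dbh, 30.0, "Fa.sy.", params)
    print(f"  dbh {dbh:4d} cm -> h = {h:6.2f} m")

table = pd.DataFrame(
    {"cellID25": [0, 0, 0], "sp": ["Fa.sy.", "Fa.sy.", "Pi.ab."],
     "n": [2, 1, 1], "dbh": [20.0, 35.0, 28.0]}
)
out = assign_heights(table, params)
print("\nGenerated cell with heights (cell Dg recomputed from the list):")
print(out.round(2))
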