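"""Summarise a field plot: basal area, quadratic mean diameter, broadleaf share.

Builds a four-tree mixed plot and prints the (BA, Dg, BA_b) triple that
drives both model calibration and plot-cell matching.
"""

from virtualforest import FieldPlot, TreeRecord

plot = FieldPlot(
    plot_id="demo",
    trees=[
        TreeRecord("Fa.sy.", dbh=25.0, weight=100.0, broadleaf=True),
        TreeRecord("Fa.sy.", dbh=35.0, weight=50.0, broadleaf=True),
        TreeRecord("Pi.ab.", dbh=30.0, weight=80.0, broadleaf=False),
        TreeRecord("Ab.al.", dbh=40.0, weight=20.0, broadleaf=False),
    ],
)
s = plot.summary()
print(f"BA   = {s.ba:.2f} m2/ha   (total stem cross-section per hectare)")
print(f"Dg   = {s.dg:.2f} cm      (diameter of the tree of mean basal area)")
print(f"BA_b = {s.ba_b:.3f}        (broadleaf share of basal area)")
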