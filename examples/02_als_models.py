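"""Fit stratified lidar prediction models and map them over a landscape.

Simulates a small landscape, fits per-stratum best-subset regressions of
BA/Dg and a logit GLM for the broadleaf share, then predicts every cell.
The printed LOOCV RMSEs are plot-level prediction errors.
"""

from virtualforest import SyntheticConfig, fit_stratified, loocv_rmse, map_predict, simulate_landscape

cfg = SyntheticConfig(nx=10, ny=10, n_plots=60, seed=7)
land = simulate_landscape(cfg)
metric_cols = ["m_ba", "m_dg", "m_bab", "noise0", "noise1"]

sets = {}
for var in ("BA", "Dg", "BA_b"):
    sets[var] = fit_stratified(
        land.plot_table, metric_cols, var, max_vars=2, min_plots=20
    )
    r = loocv_rmse(
        land.plot_table, metric_cols, var, max_vars=2, min_plots=20
    )
    model = next(iter(sets[var].models.values()), sets[var].fallback)
    print(f"{var:5s} LOOCV RMSE = {r:6.3f}   metrics: {model.selected_metrics}")

pred = map_predict(sets, land.cell_metrics)
print("\nPer-cell predictions (head):")
print(pred.head().round(2))
print("Forest cells predicted:", pred["BA"].notna().sum())
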