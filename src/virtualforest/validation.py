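"""Evaluation of generated landscapes.

Three complementary checks:

* a leave-one-out cross-validation of the whole workflow — each field
  plot is excluded from model fitting *and* from the matching pool, its
  cell is predicted and downscaled, and the generated stand is compared
  with the observed one (BA, Dg, BA_b, the 95th diameter percentile and
  the 50th/95th height percentiles, all stem-weighted);
* agreement of species composition: landscape-level species abundance in
  basal area, and the frequency at which the generated main species
  matches the observed one per cell;
* dominant heights: the mean height of the six tallest generated trees
  per cell (Hdom_T) regressed on the lidar dominant height (Hdom_ALS).
  Lidar metrics may correlate with Hdom_ALS by construction, so this
  comparison must be interpreted with caution; the report says so.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import FieldPlot, stand_summary
from .downscale import CELLS_PER_HA, cell_rng, generate_cell, joint_minmax_scale, match_plot
from .errors import InvalidInputError
from .heights import HeightModelParams, assign_heights
from .models import fit_stratified, predict
from .core import StandSummary

__all__ = [
    "ValidationReport",
    "rmse",
    "weighted_quantile",
    "loocv_workflow",
    "species_abundance",
    "main_species_match",
    "hdom_t",
    "hdom_comparison",
]

logger = logging.getLogger(__name__)

HDOM_CAVEAT = (
    "Hdom_ALS is itself derived from the lidar data the prediction models "
    "use; the Hdom_T vs Hdom_ALS comparison must be interpreted with caution."
)


@dataclass
class ValidationReport:
    """Aggregated whole-workflow validation results."""

    rmse: dict[str, float] = field(default_factory=dict)
    model_rmse: dict[str, float] = field(default_factory=dict)  # ALS models alone
    abundance: pd.DataFrame | None = None
    main_species_match_pct: float | None = None
    hdom: dict[str, float] | None = None
    n_folds: int = 0
    n_failed: int = 0
    notes: list[str] = field(default_factory=list)


def rmse(observed, predicted) -> float:
    """Root mean square error between two equally long vectors."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size == 0:
        raise InvalidInputError("observed and predicted must be equal, non-empty")
    return float(np.sqrt(np.mean((o - p) ** 2)))


def weighted_quantile(values, weights, q: float) -> float:
    """Left-continuous inverse of the weighted ECDF at probability ``q``.

    Returns the smallest value x with F(x) >= q, F being the cumulative
    share of weight at or below x.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise InvalidInputError("empty sample")
    if np.any(w < 0) or w.sum() <= 0:
        raise InvalidInputError("weights must be non-negative with positive sum")
    order = np.argsort(v, kind="mergesort")
    v, w = v[order], w[order]
    cdf = np.cumsum(w) / w.sum()
    idx = int(np.searchsorted(cdf, q, side="left"))
    return float(v[min(idx, v.size - 1)])


def _generated_summary(asg, broadleaf_map):
    """(BA, Dg, BA_b) per hectare of a generated cell's tree list."""
    if not asg.trees:
        return 0.0, 0.0, 0.0
    n = np.array([t.n for t in asg.trees], dtype=float)
    d = np.array([t.dbh for t in asg.trees], dtype=float)
    ba_i = np.pi * d**2 / 40000.0
    ba = float(np.sum(n * ba_i) * CELLS_PER_HA)
    dg = float(np.sqrt(np.sum(n * d**2) / np.sum(n)))
    bl = np.array([broadleaf_map[t.species] for t in asg.trees])
    bab = float(np.sum((n * ba_i)[bl]) / np.sum(n * ba_i))
    return ba, dg, bab


def loocv_workflow(
    plots: list[FieldPlot],
    plot_table: pd.DataFrame,
    metric_cols: list[str],
    broadleaf_map: dict[str, bool],
    height_params: HeightModelParams,
    seed: int = 0,
    transform: str = "none",
    max_vars: int = 6,
    min_plots: int = 30,
    refit_models: bool = True,
    exclude_pseudo: bool = True,
) -> ValidationReport:
    """Whole-workflow leave-one-out cross-validation.

    ``plot_table`` holds one row per plot (aligned with ``plots``) with
    the observed summaries (columns ``BA``, ``Dg``, ``BA_b``), a
    ``stratum`` column and the co-located lidar metric columns. For every
    fold the held-out plot is absent from both the regression fits (when
    ``refit_models``, the default; otherwise fixed models fitted once on
    all plots are reused) and the plot-matching pool. The report carries
    both the workflow RMSEs and the plain model LOOCV RMSEs computed on
    the same folds, so the error added by the downscaling step is
    directly readable.
    """
    if len(plots) != len(plot_table):
        raise InvalidInputError("plots and plot_table must align")
    if len(plots) < 3:
        raise InvalidInputError("need at least 3 plots for LOOCV")
    by_id = {p.plot_id: p for p in plots}
    variables = ["BA", "Dg", "BA_b"]
    have_heights = all(
        t.height is not None for p in plots for t in p.trees
    ) and len(plots) > 0

    fixed_sets = None
    if not refit_models:
        fixed_sets = {
            v: fit_stratified(
                plot_table, metric_cols, v,
                transform=(transform if v != "BA_b" else "none"),
                max_vars=max_vars, min_plots=min_plots,
            )
            for v in variables
        }

    obs: dict[str, list[float]] = {k: [] for k in
                                   ["BA", "Dg", "BA_b", "dbhQ0.95", "hQ0.5", "hQ0.95"]}
    gen: dict[str, list[float]] = {k: [] for k in obs}
    model_pred: dict[str, list[float]] = {v: [] for v in variables}
    matches: list[bool] = []
    abundance_obs: dict[str, float] = {}
    abundance_gen: dict[str, float] = {}
    n_failed = 0

    for i in range(len(plots)):
        held = plots[i]
        train_tbl = plot_table.drop(plot_table.index[i])
        test_row = plot_table.iloc[[i]]
        pool = [p for j, p in enumerate(plots) if j != i and p.trees]
        try:
            if refit_models:
                sets = {
                    v: fit_stratified(
                        train_tbl, metric_cols, v,
                        transform=(transform if v != "BA_b" else "none"),
                        max_vars=max_vars, min_plots=min_plots,
                    )
                    for v in variables
                }
            else:
                sets = fixed_sets
            stratum = str(test_row["stratum"].iloc[0])
            pred = {
                v: float(predict(sets[v].model_for(stratum), test_row)[0])
                for v in variables
            }
            pred["BA"] = max(pred["BA"], 0.0)
            pred["Dg"] = max(pred["Dg"], 1.0)
            pred["BA_b"] = min(max(pred["BA_b"], 0.0), 1.0)
            summ = StandSummary(pred["BA"], pred["Dg"], pred["BA_b"])

            space = joint_minmax_scale([summ], pool)
            pid, dist = match_plot(space.cell_scaled[0], space)
            assert pid != held.plot_id  # held-out plot must not be matchable
            asg = generate_cell(i, summ, by_id[pid], cell_rng(seed, i), dist)

            table = pd.DataFrame(
                [(i, t.species, t.n, t.dbh) for t in asg.trees],
                columns=["cellID25", "sp", "n", "dbh"],
            )
            table = assign_heights(table, height_params)
        except Exception as exc:
            logger.warning("LOOCV fold %d failed: %s", i, exc)
            n_failed += 1
            continue

        o = stand_summary(held.trees)
        g_ba, g_dg, g_bab = _generated_summary(asg, broadleaf_map)
        obs["BA"].append(o.ba); gen["BA"].append(g_ba)
        obs["Dg"].append(o.dg); gen["Dg"].append(g_dg)
        obs["BA_b"].append(o.ba_b); gen["BA_b"].append(g_bab)
        for v in variables:
            model_pred[v].append(pred[v])

        od = np.array([t.dbh for t in held.trees])
        ow = np.array([t.weight for t in held.trees])
        if len(table):
            gd = table["dbh"].to_numpy()
            gn = table["n"].to_numpy(float)
            obs["dbhQ0.95"].append(weighted_quantile(od, ow, 0.95))
            gen["dbhQ0.95"].append(weighted_quantile(gd, gn, 0.95))
            if have_heights:
                oh = np.array([t.height for t in held.trees])
                gh = table["h"].to_numpy()
                for q, key in ((0.5, "hQ0.5"), (0.95, "hQ0.95")):
                    obs[key].append(weighted_quantile(oh, ow, q))
                    gen[key].append(weighted_quantile(gh, gn, q))

        # composition bookkeeping
        held_trees = [t for t in held.trees if not (exclude_pseudo and t.pseudo)]
        for t in held_trees:
            abundance_obs[t.species] = (
                abundance_obs.get(t.species, 0.0) + t.weight * t.basal_area
            )
        for t in asg.trees:
            abundance_gen[t.species] = (
                abundance_gen.get(t.species, 0.0)
                + t.n * CELLS_PER_HA * np.pi * t.dbh**2 / 40000.0
            )
        matches.append(
            _main_species(held_trees) == _main_species_generated(asg.trees)
        )

    report = ValidationReport(n_folds=len(obs["BA"]), n_failed=n_failed)
    if n_failed:
        report.notes.append(f"{n_failed} folds failed and were skipped")
    for key in obs:
        if obs[key]:
            report.rmse[key] = rmse(obs[key], gen[key])
    for v in variables:
        if model_pred[v]:
            report.model_rmse[v] = rmse(obs[v], model_pred[v])
    species = sorted(set(abundance_obs) | set(abundance_gen))
    report.abundance = pd.DataFrame(
        {
            "species": species,
            "observed_ba": [abundance_obs.get(s, 0.0) for s in species],
            "generated_ba": [abundance_gen.get(s, 0.0) for s in species],
        }
    )
    if matches:
        report.main_species_match_pct = 100.0 * float(np.mean(matches))
    report.notes.append(HDOM_CAVEAT)
    return report


def _main_species(trees) -> str | None:
    """Most abundant species by basal area; ties by species-code order."""
    tot: dict[str, float] = {}
    for t in trees:
        tot[t.species] = tot.get(t.species, 0.0) + t.weight * t.basal_area
    if not tot:
        return None
    return min(tot, key=lambda s: (-tot[s], s))


def _main_species_generated(trees) -> str | None:
    tot: dict[str, float] = {}
    for t in trees:
        tot[t.species] = tot.get(t.species, 0.0) + t.n * np.pi * t.dbh**2 / 40000.0
    if not tot:
        return None
    return min(tot, key=lambda s: (-tot[s], s))


def species_abundance(
    plots: list[FieldPlot],
    generated: pd.DataFrame,
    dbh_min: float | None = None,
    exclude_pseudo: bool = True,
) -> pd.DataFrame:
    """Landscape-level observed vs generated basal area per species.

    ``dbh_min`` drops trees at or below that diameter from both sides
    (used where small trees were only counted by class, not identified).
    Pseudo-species records stand for such counted classes and are
    excluded by default.
    """
    obs: dict[str, float] = {}
    for p in plots:
        for t in p.trees:
            if exclude_pseudo and t.pseudo:
                continue
            if dbh_min is not None and t.dbh <= dbh_min:
                continue
            obs[t.species] = obs.get(t.species, 0.0) + t.weight * t.basal_area
    gen: dict[str, float] = {}
    if len(generated):
        g = generated
        if dbh_min is not None:
            g = g[g["dbh"] > dbh_min]
        for row in g.itertuples(index=False):
            gen[row.sp] = gen.get(row.sp, 0.0) + row.n * np.pi * row.dbh**2 / 40000.0
    species = sorted(set(obs) | set(gen))
    return pd.DataFrame(
        {
            "species": species,
            "observed_ba": [obs.get(s, 0.0) for s in species],
            "generated_ba": [gen.get(s, 0.0) for s in species],
        }
    )


def main_species_match(pairs: list[tuple[list, list]]) -> float:
    """Share (%) of paired (observed trees, generated trees) lists whose
    basal-area-dominant species coincide."""
    if not pairs:
        raise InvalidInputError("no pairs")
    hits = [
        _main_species(o) == _main_species_generated(g) for o, g in pairs
    ]
    return 100.0 * float(np.mean(hits))


def hdom_t(cell_tree_list: pd.DataFrame) -> float:
    """Dominant height of a generated cell: mean of the six tallest stems.

    A row with n stems counts n times; fewer than six stems -> mean of
    all; empty cell -> NaN.
    """
    if len(cell_tree_list) == 0:
        return float("nan")
    if "h" not in cell_tree_list.columns:
        raise InvalidInputError("heights not assigned")
    expanded = cell_tree_list.sort_values("h", ascending=False)
    heights: list[float] = []
    for row in expanded.itertuples(index=False):
        take = min(int(row.n), 6 - len(heights))
        heights.extend([float(row.h)] * take)
        if len(heights) >= 6:
            break
    return float(np.mean(heights))


def hdom_comparison(hdom_als_values, hdom_t_values) -> dict[str, float | str]:
    """OLS of Hdom_T on Hdom_ALS: slope, intercept, R2, RMSE (paired cells)."""
    x = np.asarray(hdom_als_values, dtype=float)
    y = np.asarray(hdom_t_values, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InvalidInputError("need >= 3 paired dominant heights")
    if np.ptp(x) == 0:
        raise InvalidInputError("Hdom_ALS values are constant; regression undefined")
    fit = sstats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
        "rmse": rmse(x, y),
        "caveat": HDOM_CAVEAT,
    }
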