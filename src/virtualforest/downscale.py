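"""Downscaling: turn per-cell (BA, Dg, BA_b) predictions into tree lists.

Each 25x25 m cell is matched to the most similar field plot in the scaled
(BA, Dg, BA_b) space, and the plot's tree list is transformed so the cell
exactly attains its predicted basal area and broadleaf share:

1. all plot diameters are multiplied by ``alpha = Dg_cell / Dg_plot`` so
   the transformed list has exactly the cell's quadratic mean diameter;
2. each tree record receives a target basal area obtained by cascading
   the cell BA through the broadleaf/conifer split, the species share
   within its class in the plot, and the tree share within its species
   (so the targets sum exactly to the cell BA);
3. the per-hectare stem weight follows from the target basal area and
   the corrected diameter, is divided by 16 (ha -> 625 m2 cell), and is
   rounded to an integer by a Bernoulli draw on its fractional part —
   which is unbiased, unlike nearest-integer rounding (a weight of 1.56
   becomes 2 with probability 0.56 and 1 with probability 0.44);
4. diameters are adjusted one last time so that the integer number of
   stems still carries the exact target basal area.

The only randomness is the Bernoulli rounding; per-cell RNG substreams
derived from (seed, cellID25) make output independent of cell order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FieldPlot, StandSummary, TreeRecord, tree_basal_area
from .errors import InvalidInputError

__all__ = [
    "MatchSpace",
    "CellAssignment",
    "GeneratedTree",
    "joint_minmax_scale",
    "match_plot",
    "alpha",
    "tree_target_ba",
    "continuous_weight",
    "cell_weight",
    "bernoulli_round",
    "final_dbh",
    "generate_cell",
    "generate_landscape",
    "cell_rng",
    "CELLS_PER_HA",
]

logger = logging.getLogger(__name__)

#: Surface-area ratio between 1 ha and a 25x25 m cell.
CELLS_PER_HA = 16.0


@dataclass
class MatchSpace:
    """Cells and plots jointly min-max scaled into the unit cube.

    Scaling each of BA, Dg, BA_b by the joint (cells + plots) min/max puts
    the three axes on comparable footing; a degenerate constant coordinate
    maps to 0 everywhere.
    """

    cell_scaled: np.ndarray  # (n_cells, 3)
    plot_scaled: np.ndarray  # (n_plots, 3)
    plot_ids: list[str]
    plot_forest_types: list[str | None]
    lo: np.ndarray
    hi: np.ndarray


def joint_minmax_scale(
    cell_summaries: list[StandSummary] | np.ndarray,
    plots: list[FieldPlot],
) -> MatchSpace:
    """Scale cell and plot (BA, Dg, BA_b) triples jointly to [0, 1]."""
    cells = np.asarray(
        [s.as_tuple() if isinstance(s, StandSummary) else s for s in cell_summaries],
        dtype=float,
    ).reshape(-1, 3)
    psum = np.asarray([p.summary().as_tuple() for p in plots], dtype=float).reshape(
        -1, 3
    )
    if cells.shape[0] == 0 or psum.shape[0] == 0:
        raise InvalidInputError("need at least one cell and one plot")
    both = np.vstack([cells, psum])
    lo, hi = both.min(axis=0), both.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)  # constant coordinate -> all zeros

    def scale(a):
        return (a - lo) / span

    return MatchSpace(
        cell_scaled=scale(cells),
        plot_scaled=scale(psum),
        plot_ids=[p.plot_id for p in plots],
        plot_forest_types=[p.forest_type for p in plots],
        lo=lo,
        hi=hi,
    )


def match_plot(
    cell_scaled: np.ndarray,
    space: MatchSpace,
    forest_type: str | None = None,
) -> tuple[str, float]:
    """Nearest plot (Euclidean, scaled space), optionally same forest type.

    Ties break on the smallest plot id; if no plot of the requested forest
    type exists the match falls back to the unconstrained pool with a
    logged warning. Returns ``(plot_id, distance)``.
    """
    cand = np.arange(len(space.plot_ids))
    if forest_type is not None:
        mask = np.asarray([ft == forest_type for ft in space.plot_forest_types])
        if mask.any():
            cand = cand[mask]
        else:
            logger.warning(
                "no plot of forest type %r; falling back to unconstrained match",
                forest_type,
            )
    d = np.linalg.norm(space.plot_scaled[cand] - np.asarray(cell_scaled), axis=1)
    dmin = d.min()
    tied = cand[np.isclose(d, dmin, rtol=0.0, atol=1e-12)]
    best = min(tied, key=lambda i: space.plot_ids[i])
    return space.plot_ids[best], float(dmin)


def alpha(dg_als: float, dg_f: float) -> float:
    """Diameter correction ratio alpha = Dg_cell / Dg_plot.

    Multiplying every plot dbh by alpha makes the plot's quadratic mean
    diameter equal the cell's exactly.
    """
    if dg_f <= 0:
        raise InvalidInputError("matched plot has Dg <= 0 (empty plots must not match)")
    if dg_als <= 0:
        raise InvalidInputError("cell Dg must be > 0")
    return dg_als / dg_f


def tree_target_ba(
    ba_als: float,
    ba_b_als: float,
    plot: FieldPlot,
) -> tuple[dict[int, float], float]:
    """Per-record target basal areas that sum exactly to the cell BA.

    For record i: ba_i = BA_cell * P_class * P_species|class * P_tree|species,
    where P_class is the cell broadleaf share (conifers: 1 - share) and
    the two plot-level shares are basal-area weighted. When the cell asks
    for a class the plot lacks, that class's BA is reallocated to the
    available class (keeping the total exact) and the reallocated amount
    is returned alongside.

    Returns ``(targets keyed by record position, reallocated class BA)``.
    """
    trees = plot.trees
    if not trees:
        raise InvalidInputError(f"plot {plot.plot_id} has no trees")
    w = np.array([t.weight for t in trees])
    ba_i = np.array([t.basal_area for t in trees]) * w  # stand-level ba share basis
    bl = np.array([t.broadleaf for t in trees])
    class_tot = {True: float(ba_i[bl].sum()), False: float(ba_i[~bl].sum())}
    class_target = {True: ba_als * ba_b_als, False: ba_als * (1.0 - ba_b_als)}

    reallocated = 0.0
    for cls in (True, False):
        if class_target[cls] > 0 and class_tot[cls] == 0.0:
            other = not cls
            if class_tot[other] == 0.0:
                raise InvalidInputError(f"plot {plot.plot_id} has no basal area")
            logger.warning(
                "plot %s lacks %s trees; reallocating %.3f m2/ha to the other class",
                plot.plot_id,
                "broadleaf" if cls else "coniferous",
                class_target[cls],
            )
            reallocated += class_target[cls]
            class_target[other] += class_target[cls]
            class_target[cls] = 0.0

    # species totals within class
    sp_tot: dict[tuple[bool, str], float] = {}
    for i, t in enumerate(trees):
        key = (bool(bl[i]), t.species)
        sp_tot[key] = sp_tot.get(key, 0.0) + float(ba_i[i])

    targets: dict[int, float] = {}
    for i, t in enumerate(trees):
        cls = bool(bl[i])
        if class_tot[cls] == 0.0:
            targets[i] = 0.0
            continue
        p_sp = sp_tot[(cls, t.species)] / class_tot[cls]
        p_tree = float(ba_i[i]) / sp_tot[(cls, t.species)]
        targets[i] = class_target[cls] * p_sp * p_tree
    return targets, reallocated


def continuous_weight(ba_tree: float, alpha_: float, dbh_f: float) -> float:
    """Stems/ha carrying ``ba_tree`` at the corrected diameter alpha*dbh_F.

    omega = 40000/pi * ba_tree / (alpha * dbh_F)**2, i.e. the number of
    stems of that diameter whose summed basal area is ba_tree per hectare.
    """
    if ba_tree < 0 or alpha_ <= 0 or dbh_f <= 0:
        raise InvalidInputError("tree target ba must be >= 0, alpha and dbh > 0")
    return 40000.0 / math.pi * ba_tree / (alpha_ * dbh_f) ** 2


def cell_weight(omega: float) -> float:
    """Per-cell stem weight: omega / 16 (1 ha holds sixteen 625 m2 cells)."""
    if omega < 0:
        raise InvalidInputError("omega must be >= 0")
    return omega / CELLS_PER_HA


def bernoulli_round(weight: float, rng: np.random.Generator) -> int:
    """Unbiased integer rounding: floor + Bernoulli(fractional part).

    E[result] = weight, unlike nearest-integer rounding which is biased
    because fractional cell weights are deterministic artefacts of the
    plot-to-cell area ratio (one tree on 400 m2 is always 1.5625 per cell,
    and would always round to 2).
    """
    if weight < 0:
        raise InvalidInputError("weight must be >= 0")
    base = math.floor(weight)
    frac = weight - base
    return int(base + (1 if rng.random() < frac else 0))


def final_dbh(ba_tree: float, omega_int: int) -> float:
    """Diameter at which omega_int stems per cell carry exactly ba_tree.

    dbh = sqrt(40000/pi * ba_tree / (16 * omega_int)); this compensates
    the basal-area shift introduced by integer rounding, so the change
    from alpha*dbh_F is minor.
    """
    if omega_int < 1:
        raise InvalidInputError("omega_int must be >= 1 (zero-weight trees are dropped)")
    if ba_tree <= 0:
        raise InvalidInputError("tree target basal area must be > 0")
    return math.sqrt(40000.0 / math.pi * ba_tree / (CELLS_PER_HA * omega_int))


@dataclass(frozen=True)
class GeneratedTree:
    """One output row: n identical stems of one species in one cell."""

    species: str
    n: int
    dbh: float
    height: float | None = None


@dataclass
class CellAssignment:
    """Diagnostics of one cell's generation."""

    cell_id: int
    plot_id: str
    distance: float
    alpha: float
    lost_ba: float  # summed target ba of trees rounded to zero stems
    reallocated_ba: float  # class BA moved because the plot lacked a class
    trees: list[GeneratedTree] = field(default_factory=list)


def cell_rng(seed: int, cell_id: int) -> np.random.Generator:
    """Independent, order-free RNG substream for one cell."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(cell_id)]))


def generate_cell(
    cell_id: int,
    cell: StandSummary,
    plot: FieldPlot,
    rng: np.random.Generator,
    distance: float = float("nan"),
) -> CellAssignment:
    """Transform ``plot``'s tree list to attain ``cell``'s BA and BA_b.

    All diameter targets are deterministic; only the integer stem counts
    depend on ``rng``. Trees whose Bernoulli draw lands on zero stems are
    dropped and their basal area reported in ``lost_ba``.
    """
    if cell.ba <= 0:
        return CellAssignment(cell_id, plot.plot_id, distance, 1.0, 0.0, 0.0, [])
    a = alpha(cell.dg, plot.summary().dg)
    targets, reallocated = tree_target_ba(cell.ba, cell.ba_b, plot)
    rows: list[GeneratedTree] = []
    lost = 0.0
    for i, tree in enumerate(plot.trees):
        ba_t = targets[i]
        if ba_t <= 0:
            continue
        omega = continuous_weight(ba_t, a, tree.dbh)
        w_cell = cell_weight(omega)
        n = bernoulli_round(w_cell, rng)
        if n < 1:
            lost += ba_t
            continue
        rows.append(GeneratedTree(species=tree.species, n=n, dbh=final_dbh(ba_t, n)))
    return CellAssignment(
        cell_id, plot.plot_id, distance, a, lost, reallocated, rows
    )


def generate_landscape(
    cell_table: pd.DataFrame,
    plots: list[FieldPlot],
    seed: int,
    forest_types: pd.Series | None = None,
) -> tuple[pd.DataFrame, list[CellAssignment]]:
    """Generate tree lists for every cell of a prediction table.

    ``cell_table`` is indexed by ``cellID25`` with columns ``BA``, ``Dg``,
    ``BA_b``; rows with NaN (non-forest) are skipped. Output is a tidy
    frame with columns ``cellID25, sp, n, dbh`` (heights are assigned by
    the height model afterwards), deterministic given ``seed`` and
    independent of cell ordering.
    """
    pool = [p for p in plots if p.trees]
    if not pool:
        raise InvalidInputError("no non-empty plots available for matching")
    valid = cell_table.dropna(subset=["BA", "Dg", "BA_b"])
    summaries = [
        StandSummary(float(r.BA), float(r.Dg), float(r.BA_b))
        for r in valid.itertuples()
    ]
    space = joint_minmax_scale(summaries, pool)
    by_id = {p.plot_id: p for p in pool}

    assignments: list[CellAssignment] = []
    records = []
    for k, (cell_id, summ) in enumerate(zip(valid.index, summaries)):
        ft = None
        if forest_types is not None and cell_id in forest_types.index:
            ft = forest_types.loc[cell_id]
        pid, dist = match_plot(space.cell_scaled[k], space, forest_type=ft)
        asg = generate_cell(
            int(cell_id), summ, by_id[pid], cell_rng(seed, int(cell_id)), dist
        )
        assignments.append(asg)
        for t in asg.trees:
            records.append((int(cell_id), t.species, t.n, t.dbh))
    table = pd.DataFrame(records, columns=["cellID25", "sp", "n", "dbh"])
    table = table.sort_values(["cellID25", "sp", "dbh"], kind="mergesort").reset_index(
        drop=True
    )
    return table, assignments
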