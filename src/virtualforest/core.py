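"""Domain types and stand-level summary statistics.

A forest stand is summarised by three variables that together sketch its
structure and composition:

* ``BA``   — total basal area (m2/ha), the summed cross-sectional stem area
  at breast height (1.3 m) scaled to one hectare;
* ``Dg``   — quadratic mean diameter (cm), the diameter of the tree of mean
  basal area: ``Dg**2`` equals the weighted mean of squared dbh;
* ``BA_b`` — the share of basal area contributed by broadleaf species (0-1).

These three summaries form the matching space of the downscaling algorithm
and the response variables of the lidar prediction models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "TreeRecord",
    "FieldPlot",
    "StandSummary",
    "tree_basal_area",
    "stand_summary",
    "read_plots",
    "plot_weight",
]


@dataclass(frozen=True)
class TreeRecord:
    """One measured (or generated) tree.

    Parameters
    ----------
    species
        Species code (any hashable label, e.g. ``"Fa.sy."``).
    dbh
        Diameter at breast height in cm, > 0.
    weight
        Stems per hectare this record represents, > 0. Fractional weights
        are legal before integer rounding.
    height
        Total height in m, optional; must exceed breast height (1.3 m).
    broadleaf
        Whether the species is broadleaf (``True``) or coniferous.
    pseudo
        Marks class-level records standing in for counted-but-not-measured
        small trees (midpoint dbh, pooled species); they contribute to
        stand summaries but can be excluded from composition validation.
    """

    species: str
    dbh: float
    weight: float
    height: float | None = None
    broadleaf: bool = False
    pseudo: bool = False

    def __post_init__(self) -> None:
        if not self.dbh > 0:
            raise InvalidInputError(f"dbh must be > 0, got {self.dbh}")
        if not self.weight > 0:
            raise InvalidInputError(f"weight must be > 0, got {self.weight}")
        if self.height is not None and not self.height > 1.3:
            raise InvalidInputError(
                f"height must exceed breast height (1.3 m), got {self.height}"
            )

    @property
    def basal_area(self) -> float:
        """Individual-tree basal area in m2."""
        return tree_basal_area(self.dbh)


@dataclass
class FieldPlot:
    """A field plot: its tree list plus design metadata.

    ``area_components`` describes nested designs as ``(radius_m, dbh_min,
    dbh_max)`` triples; per-hectare weights of the trees must be consistent
    with the component on which each tree was enumerated
    (``weight = 10000 / component area``).
    """

    plot_id: str
    trees: list[TreeRecord] = field(default_factory=list)
    stratum: str = "all"
    area_components: list[tuple[float, float, float]] = field(default_factory=list)
    forest_type: str | None = None

    def summary(self) -> "StandSummary":
        return stand_summary(self.trees)


@dataclass(frozen=True)
class StandSummary:
    """(BA, Dg, BA_b) triple describing a stand."""

    ba: float
    dg: float
    ba_b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ba_b <= 1.0:
            raise InvalidInputError(f"BA_b must lie in [0, 1], got {self.ba_b}")
        if self.ba < 0 or self.dg < 0:
            raise InvalidInputError("BA and Dg must be non-negative")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.ba, self.dg, self.ba_b)


def tree_basal_area(dbh: float | np.ndarray) -> float | np.ndarray:
    """Cross-sectional stem area (m2) of a tree of diameter ``dbh`` cm.

    ba = pi * (dbh / 200)**2 = pi * dbh**2 / 40000.
    """
    arr = np.asarray(dbh, dtype=float)
    if np.any(arr <= 0):
        raise InvalidInputError("dbh must be > 0")
    out = math.pi * arr**2 / 40000.0
    return float(out) if np.isscalar(dbh) or arr.ndim == 0 else out


def plot_weight(component_area_m2: float) -> float:
    """Per-hectare weight of one fully enumerated tree on a plot component."""
    if component_area_m2 <= 0:
        raise InvalidInputError("plot component area must be > 0")
    return 10000.0 / component_area_m2


def stand_summary(
    trees: "FieldPlot | Iterable[TreeRecord]",
    broadleaf_map: Mapping[str, bool] | None = None,
) -> StandSummary:
    """Compute (BA, Dg, BA_b) from a tree list.

    BA   = sum_i w_i * ba(dbh_i)
    Dg   = sqrt( sum_i w_i dbh_i^2 / sum_i w_i )
    BA_b = broadleaf BA / BA       (0 for an empty stand)

    The broadleaf class is taken from each record's ``broadleaf`` flag
    unless ``broadleaf_map`` is given, in which case every species present
    must appear in the map (a missing species raises
    :class:`~virtualforest.errors.ConfigurationError` naming it).
    """
    if isinstance(trees, FieldPlot):
        trees = trees.trees
    trees = list(trees)
    if not trees:
        return StandSummary(0.0, 0.0, 0.0)

    def is_broadleaf(t: TreeRecord) -> bool:
        if broadleaf_map is None:
            return t.broadleaf
        if t.species not in broadleaf_map:
            raise ConfigurationError(
                f"species {t.species!r} missing from broadleaf classification"
            )
        return bool(broadleaf_map[t.species])

    w = np.array([t.weight for t in trees])
    d = np.array([t.dbh for t in trees])
    ba_i = np.pi * d**2 / 40000.0
    ba = float(np.sum(w * ba_i))
    dg = float(np.sqrt(np.sum(w * d**2) / np.sum(w)))
    bl = np.array([is_broadleaf(t) for t in trees])
    ba_b = float(np.sum(w[bl] * ba_i[bl]) / ba) if ba > 0 else 0.0
    # guard FP round-off at the boundaries
    ba_b = min(max(ba_b, 0.0), 1.0)
    return StandSummary(ba, dg, ba_b)


def read_plots(
    path,
    broadleaf_map: Mapping[str, bool],
    pseudo_species: Sequence[str] = (),
) -> list[FieldPlot]:
    """Read field plots from a delimited text file.

    Expected columns: ``plot_id, species, dbh_cm, weight_ha`` and optionally
    ``height_m, stratum, forest_type``. One row per tree. Species absent
    from ``broadleaf_map`` raise a configuration error.
    """
    df = pd.read_csv(path)
    required = {"plot_id", "species", "dbh_cm", "weight_ha"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"plot file missing columns: {sorted(missing)}")
    plots: dict[str, FieldPlot] = {}
    for row in df.itertuples(index=False):
        sp = str(row.species)
        if sp not in broadleaf_map:
            raise ConfigurationError(
                f"species {sp!r} missing from broadleaf classification"
            )
        pid = str(row.plot_id)
        if pid not in plots:
            plots[pid] = FieldPlot(
                plot_id=pid,
                stratum=str(getattr(row, "stratum", "all") or "all"),
                forest_type=(
                    str(row.forest_type)
                    if "forest_type" in df.columns and pd.notna(row.forest_type)
                    else None
                ),
            )
        h = getattr(row, "height_m", None)
        h = float(h) if h is not None and pd.notna(h) else None
        plots[pid].trees.append(
            TreeRecord(
                species=sp,
                dbh=float(row.dbh_cm),
                weight=float(row.weight_ha),
                height=h,
                broadleaf=bool(broadleaf_map[sp]),
                pseudo=sp in pseudo_species,
            )
        )
    return list(plots.values())
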