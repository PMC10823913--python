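"""Simplified per-cell lidar metric computation from height surfaces.

The real acquisitions derive metrics from classified point clouds; here a
cell is summarised from normalised above-ground heights (a point sample or
a canopy height model, CHM). The one metric the validation depends on is
the lidar dominant height ``Hdom_ALS``: the mean height of the six highest
CHM local maxima of a cell (mean of all maxima when fewer than six exist).
Local maxima below 5 m are discarded as shrubs/low vegetation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError

__all__ = [
    "HeightField",
    "filter_vegetation",
    "normalize_intensity",
    "point_metrics",
    "local_maxima",
    "hdom_als",
    "HDOM_UNDEFINED",
    "VEGETATION_HEIGHT_CUT",
    "MAXIMA_HEIGHT_CUT",
]

#: Points at or below this height (m) are shrubs/low vegetation, not canopy.
VEGETATION_HEIGHT_CUT = 2.0
#: CHM local maxima below this height (m) are discarded.
MAXIMA_HEIGHT_CUT = 5.0
#: Sentinel returned by :func:`hdom_als` for a cell without maxima.
HDOM_UNDEFINED = float("nan")


@dataclass
class HeightField:
    """A grid of above-ground heights (m) covering one or more 25 m cells.

    ``resolution`` is the grid spacing in m and must divide the 25 m cell
    size; heights are expected normalised (>= 0).
    """

    heights: np.ndarray
    resolution: float = 1.0

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise InvalidInputError("height field must be a 2-D grid")
        if not math.isclose(25.0 / self.resolution, round(25.0 / self.resolution)):
            raise InvalidInputError(
                f"grid resolution {self.resolution} m must divide the 25 m cell"
            )


def filter_vegetation(
    heights: np.ndarray,
    scan_angles: np.ndarray | None = None,
    angle_cut: float | None = None,
) -> np.ndarray:
    """Retain vegetation points: height strictly above 2 m.

    When ``scan_angles`` and ``angle_cut`` (degrees) are given, points with
    |angle| strictly larger than the cut are dropped first (the default cut
    used on noisy acquisitions is 21 degrees).
    """
    h = np.asarray(heights, dtype=float)
    keep = np.ones(h.shape, dtype=bool)
    if scan_angles is not None and angle_cut is not None:
        keep &= np.abs(np.asarray(scan_angles, dtype=float)) <= angle_cut
    keep &= h > VEGETATION_HEIGHT_CUT
    return h[keep]


def normalize_intensity(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Z-score ``values`` using the mean and sd of ``reference``.

    The sd is the population standard deviation (ddof=0), so a two-point
    reference ``[1, 3]`` maps onto ``[-1, 1]``. Intensities are normalised
    per acquisition so that datasets with different sensors are comparable.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size < 2 or np.unique(ref).size < 2:
        raise InvalidInputError("reference set needs >= 2 distinct values")
    sd = float(np.std(ref))
    if sd == 0.0:
        raise InvalidInputError("reference intensity sd is zero")
    return (np.asarray(values, dtype=float) - float(np.mean(ref))) / sd


def point_metrics(heights: np.ndarray, n_total: int | None = None) -> dict[str, float]:
    """Generic point-cloud summary metrics for one cell.

    Returns mean, sd, deciles p10..p90 (linear interpolation between order
    statistics) and canopy cover — the fraction of all returns above the
    2 m vegetation cut, which needs ``n_total``, the pre-filter count.
    An empty input yields an all-zero vector with ``empty=1.0``.
    """
    h = np.asarray(heights, dtype=float)
    names = ["mean", "sd"] + [f"p{q}" for q in range(10, 100, 10)] + ["cover"]
    if h.size == 0:
        out = {k: 0.0 for k in names}
        out["empty"] = 1.0
        return out
    out = {"mean": float(np.mean(h)), "sd": float(np.std(h))}
    qs = np.percentile(h, np.arange(10, 100, 10), method="linear")
    for q, v in zip(range(10, 100, 10), qs):
        out[f"p{q}"] = float(v)
    n_tot = n_total if n_total is not None else h.size
    out["cover"] = float(np.sum(h > VEGETATION_HEIGHT_CUT) / n_tot) if n_tot else 0.0
    out["empty"] = 0.0
    return out


def local_maxima(
    chm: HeightField | np.ndarray, height_cut: float = MAXIMA_HEIGHT_CUT
) -> list[tuple[int, int, float]]:
    """Strict local maxima of a CHM over the 8-neighbourhood.

    A pixel is a maximum only if strictly greater than all eight
    neighbours, so plateaus and ties are never maxima (deterministic).
    Maxima below ``height_cut`` (default 5 m) are discarded.
    """
    grid = chm.heights if isinstance(chm, HeightField) else np.asarray(chm, float)
    if not np.all(np.isfinite(grid)):
        raise InvalidInputError("CHM contains non-finite heights")
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neigh_max = ndimage.maximum_filter(
        grid, footprint=footprint, mode="constant", cval=-np.inf
    )
    mask = (grid > neigh_max) & (grid >= height_cut)
    rows, cols = np.nonzero(mask)
    return [(int(r), int(c), float(grid[r, c])) for r, c in zip(rows, cols)]


def hdom_als(maxima_heights) -> float:
    """Lidar dominant height: mean of the six highest local maxima.

    With fewer than six maxima the mean of all of them is used; an empty
    input returns NaN (undefined).
    """
    h = np.asarray([m[2] if isinstance(m, tuple) else m for m in maxima_heights], float)
    if h.size == 0:
        return HDOM_UNDEFINED
    top = np.sort(h)[-6:]
    return float(np.mean(top))
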