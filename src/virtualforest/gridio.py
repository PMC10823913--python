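"""ESRI ASCII grid (.asc) reading and writing.

The published cell-ID rasters use this plain-text format: a six-line
header (``ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value``)
followed by whitespace-separated values, row-major from the north-west
corner — the same convention cellID25 numbering follows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = ["AsciiGrid", "read_ascii_grid", "write_ascii_grid", "cell_id_grid"]

CELL_SIZE = 25.0


@dataclass
class AsciiGrid:
    """Grid values plus georeferencing header."""

    values: np.ndarray  # (nrows, ncols), NODATA as NaN
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = CELL_SIZE
    nodata: float = -9999.0


def read_ascii_grid(path, require_cellsize: float | None = None) -> AsciiGrid:
    """Parse an ESRI ASCII grid; NODATA values come back as NaN.

    ``require_cellsize`` enforces the resolution (25 m for cell-ID
    rasters); a mismatch or malformed header raises a descriptive error.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines[:6]:
        parts = line.split()
        if len(parts) != 2:
            break
        key = parts[0].lower()
        if key not in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
            break
        header[key] = float(parts[1])
        n_header += 1
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise InvalidInputError(f"malformed .asc header: missing {req!r}")
    if require_cellsize is not None and not np.isclose(
        header["cellsize"], require_cellsize
    ):
        raise InvalidInputError(
            f"expected {require_cellsize} m cells, got {header['cellsize']}"
        )
    try:
        values = np.loadtxt(lines[n_header:], dtype=float, ndmin=2)
    except ValueError as exc:
        raise InvalidInputError(f"malformed .asc data block: {exc}") from exc
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise InvalidInputError(
            f"data block shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    return AsciiGrid(
        values=values,
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        cellsize=header["cellsize"],
        nodata=nodata,
    )


def write_ascii_grid(grid: AsciiGrid, path) -> None:
    """Write an ESRI ASCII grid; NaNs become the NODATA value."""
    vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {vals.shape[1]}\n")
        fh.write(f"nrows {vals.shape[0]}\n")
        fh.write(f"xllcorner {grid.xllcorner:g}\n")
        fh.write(f"yllcorner {grid.yllcorner:g}\n")
        fh.write(f"cellsize {grid.cellsize:g}\n")
        fh.write(f"NODATA_value {grid.nodata:g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def cell_id_grid(nrows: int, ncols: int, **kwargs) -> AsciiGrid:
    """cellID25 raster: ids assigned row-major from the north-west corner."""
    ids = np.arange(nrows * ncols, dtype=float).reshape(nrows, ncols)
    return AsciiGrid(values=ids, **kwargs)
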