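"""ESRI ASCII grid I/O.

Rasters are persisted as ESRI ASCII grids (.asc): a six-line header followed
by the cell matrix, top row first.  The format is plain text and round-trips
through any GIS.  Internally arrays are stored with row 0 at the bottom
(south), so rows are flipped on write/read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .grid import GridSpec

NODATA = -9999.0


def write_ascii_grid(path: str | Path, grid: GridSpec, values: np.ndarray, nodata: float = NODATA) -> None:
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.nrows, grid.ncols):
        raise ValueError("raster shape does not match grid")
    out = np.where(np.isfinite(values), values, nodata)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.x0}\n"
        f"yllcorner {grid.y0}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI ASCII stores the top (northern) row first
        np.savetxt(fh, out[::-1], fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Return (values, header) with NODATA mapped to NaN, row 0 = south."""
    header: dict = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1].copy()
    nodata = header.get("nodata_value")
    if nodata is not None:
        data[data == nodata] = np.nan
    return data, header


def grid_from_header(header: dict, land: np.ndarray) -> GridSpec:
    return GridSpec(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        land=land,
        cell_size=float(header["cellsize"]),
        x0=float(header["xllcorner"]),
        y0=float(header["yllcorner"]),
    )
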