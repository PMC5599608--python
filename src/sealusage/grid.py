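"""Analysis grid and covariate containers.

The analysis raster is a regular grid of square cells (600 m by default, the
resolution implied by the median two-hourly step length of tagged harbour
seals).  Cell (0, 0) sits at the lower-left corner; each cell covers the
half-open interval [x, x + cell) x [y, y + cell).  Arrays are indexed
``[row, col]`` with row 0 the southernmost row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

DEFAULT_CELL_M = 600.0

#: relative offsets of the 16-neighbourhood (queen + knight moves) together
#: with the intermediate cells a move passes over (which must be sea) and the
#: centre-to-centre distance in cell units.
NEIGHBOURS_16: list[tuple[int, int, tuple[tuple[int, int], ...], float]] = []


def _build_neighbours() -> None:
    offsets = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            offsets.append((dr, dc))
    for dr, dc in [(1, 2), (2, 1), (-1, 2), (-2, 1), (1, -2), (2, -1), (-1, -2), (-2, -1)]:
        offsets.append((dr, dc))
    for dr, dc in offsets:
        if abs(dr) + abs(dc) == 1:
            inter: tuple[tuple[int, int], ...] = ()
        elif abs(dr) == 1 and abs(dc) == 1:
            inter = ((dr, 0), (0, dc))
        elif abs(dc) == 2:  # knight, long axis = columns
            sr, sc = (1 if dr > 0 else -1), (1 if dc > 0 else -1)
            inter = ((0, sc), (sr, sc))
        else:  # knight, long axis = rows
            sr, sc = (1 if dr > 0 else -1), (1 if dc > 0 else -1)
            inter = ((sr, 0), (sr, sc))
        NEIGHBOURS_16.append((dr, dc, inter, float(np.hypot(dr, dc))))


_build_neighbours()


@dataclass
class GridSpec:
    """A regular raster with a boolean land mask.

    Parameters
    ----------
    nrows, ncols
        Grid dimensions.
    land
        Boolean array of shape ``(nrows, ncols)``; True marks land.
    cell_size
        Cell edge length in metres.
    x0, y0
        Projected coordinates of the lower-left corner of cell (0, 0).
    """

    nrows: int
    ncols: int
    land: np.ndarray
    cell_size: float = DEFAULT_CELL_M
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        self.land = np.asarray(self.land, dtype=bool)
        if self.land.shape != (self.nrows, self.ncols):
            raise ValueError("land mask shape does not match grid dimensions")

    # -- basic queries ---------------------------------------------------
    @property
    def sea(self) -> np.ndarray:
        return ~self.land

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map projected coordinates to (row, col); half-open cell intervals."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(int)
        return row, col

    def centre_of(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y0 + (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def in_bounds(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of cell-centre coordinates, shape (nrows, ncols)."""
        rows, cols = np.mgrid[0 : self.nrows, 0 : self.ncols]
        return self.centre_of(rows, cols)

    def sea_cells(self) -> np.ndarray:
        """(k, 2) array of (row, col) indices of sea cells, row-major order."""
        return np.argwhere(self.sea)

    def coastal_land_cells(self) -> np.ndarray:
        """Land cells 8-adjacent to at least one sea cell."""
        out = []
        for r, c in np.argwhere(self.land):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < self.nrows and 0 <= cc < self.ncols and not self.land[rr, cc]:
                        out.append((r, c))
                        break
                else:
                    continue
                break
        return np.array(out, dtype=int).reshape(-1, 2)

    def adjacent_sea(self, row: int, col: int) -> list[tuple[int, int]]:
        """Sea cells 8-adjacent to (row, col)."""
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = row + dr, col + dc
                if 0 <= rr < self.nrows and 0 <= cc < self.ncols and not self.land[rr, cc]:
                    out.append((rr, cc))
        return out

    def ravel(self, row, col):
        return np.asarray(row) * self.ncols + np.asarray(col)

    def unravel(self, idx):
        idx = np.asarray(idx)
        return idx // self.ncols, idx % self.ncols

    def signature(self) -> str:
        """Stable hash of the grid geometry and mask, for cache keys."""
        import hashlib

        h = hashlib.sha256()
        h.update(repr((self.nrows, self.ncols, self.cell_size, self.x0, self.y0)).encode())
        h.update(np.packbits(self.land).tobytes())
        return h.hexdigest()[:16]


@dataclass
class CovariateStack:
    """Named environmental covariate rasters aligned to one grid.

    Standard layer names: ``depth`` (m, positive downwards), ``current_speed``
    (m s-1), ``tidal_power`` (W m-2), ``peak_spring_flow`` / ``peak_neap_flow``
    (m s-1), ``sand`` / ``gravel`` / ``mud`` (fractions summing to one).
    """

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __setitem__(self, name: str, value: np.ndarray) -> None:
        value = np.asarray(value, dtype=float)
        if value.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError(f"layer {name!r} shape mismatch")
        self.layers[name] = value

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def names(self) -> list[str]:
        return list(self.layers)

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(self.layers.items())
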