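"""Georeferenced regular longitude/latitude grids and Esri ASCII grid I/O.

Conventions (fixed for reproducibility):

* cell indexing is row-major from the top-left (north-west) corner;
* coordinates refer to cell centres, in decimal degrees;
* a point on a cell boundary belongs to the cell whose west or north edge
  it lies on (half-open cells, west/north edge inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .geodesy import chord_to_arc_km, lonlat_to_xyz

LAND_CODE = 1
WATER_CODE = 0


@dataclass
class RasterGrid:
    """A regular lon/lat grid of numeric cell values.

    ``values`` has shape (n_rows, n_cols) with row 0 the northernmost row.
    ``xllcorner``/``yllcorner`` are the coordinates of the outer corner of
    the south-west cell (grid registration corner, Esri convention).
    """

    values: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("grid values must be a non-empty 2-D array")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    # -- basic geometry -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_cells(self) -> int:
        return self.values.size

    @property
    def ytop(self) -> float:
        return self.yllcorner + self.n_rows * self.cellsize

    @property
    def xright(self) -> float:
        return self.xllcorner + self.n_cols * self.cellsize

    def index_to_rowcol(self, index):
        index = np.asarray(index)
        if np.any((index < 0) | (index >= self.n_cells)):
            raise IndexError("cell index out of range")
        return index // self.n_cols, index % self.n_cols

    def rowcol_to_index(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        if np.any((row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)):
            raise IndexError("row/col out of range")
        return row * self.n_cols + col

    def cell_center(self, index):
        """(lon, lat) of cell centre(s) for flat index/indices."""
        row, col = self.index_to_rowcol(index)
        lon = self.xllcorner + (col + 0.5) * self.cellsize
        lat = self.ytop - (row + 0.5) * self.cellsize
        return lon, lat

    def all_centers(self):
        """(lons, lats) arrays of every cell centre in flat index order."""
        return self.cell_center(np.arange(self.n_cells))

    def contains(self, lon: float, lat: float) -> bool:
        return (self.xllcorner <= lon < self.xright) and (self.yllcorner < lat <= self.ytop)

    def lonlat_to_index(self, lon: float, lat: float) -> int:
        """Flat index of the cell containing the point (west/north edges inclusive)."""
        if not self.contains(lon, lat):
            raise ValueError(f"point ({lon}, {lat}) outside grid bounds")
        col = int(np.floor((lon - self.xllcorner) / self.cellsize))
        row = int(np.floor((self.ytop - lat) / self.cellsize))
        # a point exactly on the grid's north edge belongs to row 0
        row = min(row, self.n_rows - 1)
        col = min(col, self.n_cols - 1)
        return int(self.rowcol_to_index(row, col))

    # -- value helpers ---------------------------------------------------
    @property
    def flat(self) -> np.ndarray:
        return self.values.ravel()

    def valid_mask(self) -> np.ndarray:
        """Flat boolean mask of cells that are not nodata."""
        return ~np.isclose(self.flat, self.nodata) & ~np.isnan(self.flat)

    def land_mask(self, land_code: float = LAND_CODE) -> np.ndarray:
        return self.valid_mask() & np.isclose(self.flat, land_code)

    def water_mask(self, water_code: float = WATER_CODE) -> np.ndarray:
        return self.valid_mask() & np.isclose(self.flat, water_code)

    def like(self, values: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        """New grid with the same georeferencing and different values."""
        return RasterGrid(
            np.asarray(values, dtype=float).reshape(self.n_rows, self.n_cols),
            self.xllcorner,
            self.yllcorner,
            self.cellsize,
            self.nodata if nodata is None else nodata,
        )


def distance_to_coast(grid: RasterGrid, land_code: float = LAND_CODE) -> RasterGrid:
    """Great-circle distance (km) from each water cell centre to the nearest
    land cell centre; land cells get 0.

    Uses a KD-tree on unit-sphere Cartesian coordinates, so chord nearest
    neighbours coincide with great-circle nearest neighbours.
    """
    land = grid.land_mask(land_code)
    water = grid.valid_mask() & ~land
    out = np.zeros(grid.n_cells)
    out[~grid.valid_mask()] = grid.nodata
    if water.any():
        if not land.any():
            raise ValueError("cannot compute distance to coast: grid has no land cells")
        lons, lats = grid.all_centers()
        tree = cKDTree(lonlat_to_xyz(lons[land], lats[land]))
        chord, _ = tree.query(lonlat_to_xyz(lons[water], lats[water]))
        out[water] = chord_to_arc_km(chord)
    return grid.like(out)


# -- Esri ASCII grid I/O -----------------------------------------------

_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}


def read_ascii_grid(path) -> RasterGrid:
    """Read an Esri ASCII grid (.asc).

    Accepts the standard 5/6-line header (ncols, nrows, xllcorner, yllcorner,
    cellsize, optional NODATA_value) followed by whitespace-separated rows,
    north row first. Malformed headers raise ``ValueError`` naming the line.
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            parts = stripped.split()
            key = parts[0].lower()
            if not data_lines and (key in _HEADER_KEYS or key == "nodata_value"):
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: malformed header line {stripped!r}")
                try:
                    header[key] = float(parts[1])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric header value {parts[1]!r}"
                    ) from exc
            else:
                data_lines.append(stripped)
    missing = _HEADER_KEYS - header.keys()
    if missing:
        raise ValueError(f"{path}: missing header keys: {sorted(missing)}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    try:
        values = np.fromstring(" ".join(data_lines), sep=" ")
    except Exception as exc:  # pragma: no cover - numpy rarely raises here
        raise ValueError(f"{path}: could not parse grid body") from exc
    if values.size != nrows * ncols:
        raise ValueError(
            f"{path}: expected {nrows * ncols} values, found {values.size}"
        )
    return RasterGrid(
        values.reshape(nrows, ncols),
        header["xllcorner"],
        header["yllcorner"],
        header["cellsize"],
        header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(grid: RasterGrid, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.xllcorner:.10g}\n")
        fh.write(f"yllcorner {grid.yllcorner:.10g}\n")
        fh.write(f"cellsize {grid.cellsize:.10g}\n")
        fh.write(f"NODATA_value {grid.nodata:.10g}\n")
        for row in grid.values:
            fh.write(" ".join(f"{v:.10g}" for v in row))
            fh.write("\n")
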