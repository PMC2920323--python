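"""The landscape model: a sparse conductance matrix over grid cells.

Movement through the landscape is represented as a graph whose nodes are
grid cells and whose weighted edges hold the conductance (ease of movement,
the reciprocal of resistance/friction) between spatially adjacent cells.
Land-land connections have conductance 1; connections that involve a water
cell decay with distance from the coast:

    c = p1 * 2 ** (-dbar / p2)

where ``p1`` is the conductance of water relative to land and ``p2`` the
half-value distance in km (``dbar`` is the mean distance-to-coast of the
two connected cells, land cells contributing 0).  The water sub-matrix is
symmetrically normalized, merged with the land sub-matrix, and every entry
is then divided by the great-circle distance between the two cell centres,
which corrects both the diagonal-vs-straight bias of queen's-case moves and
the poleward shrinking of W-E cell spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geodesy import great_circle_km
from .raster import LAND_CODE, RasterGrid, distance_to_coast


@dataclass(frozen=True)
class LandscapeParams:
    """Parameters of the water-body conductance component.

    p1: conductance of water relative to land (dimensionless, >= 0).
    p2: conductance half-value distance in km (> 0).
    directions: 4 (rook) or 8 (queen's case) cell adjacency.
    """

    p1: float
    p2: float
    directions: int = 8

    def __post_init__(self) -> None:
        if self.p1 < 0:
            raise ValueError("p1 must be non-negative")
        if self.p2 <= 0:
            raise ValueError("p2 must be positive")
        if self.directions not in (4, 8):
            raise ValueError("directions must be 4 or 8")


def build_adjacency(grid: RasterGrid, directions: int = 8) -> sp.csr_matrix:
    """Unit-valued symmetric adjacency between valid (non-nodata) cells.

    ``directions=4`` connects rook neighbours, ``directions=8`` adds the
    diagonals (queen's case).
    """
    if directions not in (4, 8):
        raise ValueError("directions must be 4 or 8")
    if grid.n_cells == 0:
        raise ValueError("empty grid")
    valid = grid.valid_mask().reshape(grid.n_rows, grid.n_cols)
    idx = np.arange(grid.n_cells).reshape(grid.n_rows, grid.n_cols)
    offsets = [(0, 1), (1, 0)]
    if directions == 8:
        offsets += [(1, 1), (1, -1)]
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for dr, dc in offsets:
        if dc >= 0:
            a = idx[: grid.n_rows - dr, : grid.n_cols - dc]
            b = idx[dr:, dc:]
            ok = valid[: grid.n_rows - dr, : grid.n_cols - dc] & valid[dr:, dc:]
        else:
            a = idx[: grid.n_rows - dr, -dc:]
            b = idx[dr:, : grid.n_cols + dc]
            ok = valid[: grid.n_rows - dr, -dc:] & valid[dr:, : grid.n_cols + dc]
        rows.append(a[ok])
        cols.append(b[ok])
    i = np.concatenate(rows)
    j = np.concatenate(cols)
    m = sp.coo_matrix(
        (np.ones(i.size), (i, j)), shape=(grid.n_cells, grid.n_cells)
    ).tocsr()
    return m + m.T


def water_conductance(
    adjacency: sp.spmatrix,
    grid: RasterGrid,
    dist_to_coast: RasterGrid,
    params: LandscapeParams,
    land_code: float = LAND_CODE,
) -> sp.csr_matrix:
    """Conductance of connections that involve at least one water cell.

    Returns a matrix supported only on water-involving connections of the
    adjacency, with values p1 * 2**(-dbar/p2); land-land connections are
    absent (they keep conductance 1 elsewhere).
    """
    if params.p2 <= 0:
        raise ValueError("p2 must be positive")
    land = grid.land_mask(land_code)
    dtc = np.where(land, 0.0, dist_to_coast.flat)
    if np.any(dtc[grid.valid_mask()] < 0):
        raise ValueError("distance-to-coast must be non-negative")
    coo = sp.triu(adjacency, k=1).tocoo()
    involves_water = ~(land[coo.row] & land[coo.col])
    i, j = coo.row[involves_water], coo.col[involves_water]
    dbar = (dtc[i] + dtc[j]) / 2.0
    c = params.p1 * np.exp2(-dbar / params.p2)
    m = sp.coo_matrix((c, (i, j)), shape=adjacency.shape).tocsr()
    return m + m.T


def symmetric_normalize(m: sp.spmatrix) -> sp.csr_matrix:
    """D^(-1/2) M D^(-1/2) with D the diagonal of row sums.

    Rows/columns with zero sum pass through as zero.  The result of a
    symmetric non-negative input has all eigenvalues in [-1, 1].
    """
    m = m.tocsr()
    rowsum = np.asarray(m.sum(axis=1)).ravel()
    inv_sqrt = np.zeros_like(rowsum)
    nz = rowsum > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(rowsum[nz])
    d = sp.diags(inv_sqrt)
    return (d @ m @ d).tocsr()


def center_distances(grid: RasterGrid, m: sp.spmatrix) -> np.ndarray:
    """Great-circle distances (km) between cell centres for each stored entry
    of ``m`` (COO order)."""
    coo = m.tocoo()
    lon_i, lat_i = grid.cell_center(coo.row)
    lon_j, lat_j = grid.cell_center(coo.col)
    return great_circle_km(lon_i, lat_i, lon_j, lat_j)


def distance_correct(m: sp.spmatrix, grid: RasterGrid) -> sp.csr_matrix:
    """Divide each conductance entry by the great-circle distance between the
    two cell centres, yielding per-km conductances."""
    coo = m.tocoo()
    d = center_distances(grid, coo)
    if np.any(d <= 0):
        raise ValueError("coincident cell centres in conductance matrix")
    return sp.coo_matrix((coo.data / d, (coo.row, coo.col)), shape=m.shape).tocsr()


def assemble_landscape(
    grid: RasterGrid,
    params: LandscapeParams,
    dist_to_coast: RasterGrid | None = None,
    land_code: float = LAND_CODE,
) -> sp.csr_matrix:
    """Build the full landscape model from a landmass raster.

    Land-land connections get conductance 1; water-involving connections get
    the coastal decay conductance, symmetrically normalized as a separate
    sub-matrix; the merged matrix is then distance-corrected (per km).
    Raises if the resulting graph has no connections at all.
    """
    adjacency = build_adjacency(grid, params.directions)
    land = grid.land_mask(land_code)
    coo = sp.triu(adjacency, k=1).tocoo()
    land_land = land[coo.row] & land[coo.col]
    land_m = sp.coo_matrix(
        (np.ones(int(land_land.sum())), (coo.row[land_land], coo.col[land_land])),
        shape=adjacency.shape,
    ).tocsr()
    land_m = land_m + land_m.T

    if dist_to_coast is None:
        if land.any():
            dist_to_coast = distance_to_coast(grid, land_code)
        else:
            dist_to_coast = grid.like(np.zeros(grid.n_cells))
    water_m = water_conductance(adjacency, grid, dist_to_coast, params, land_code)
    merged = land_m + symmetric_normalize(water_m)
    merged.eliminate_zeros()
    if merged.nnz == 0:
        raise ValueError(
            "landscape graph has no connections (all-water grid with p1 = 0?)"
        )
    return distance_correct(merged, grid)
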