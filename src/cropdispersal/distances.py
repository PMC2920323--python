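"""Distance and trajectory metrics derived from a landscape model.

Three families of predictors come out of one conductance matrix:

* least-cost distances (sum of reciprocal per-km conductances along the
  cheapest path) — predict arrival ages and heterozygosity;
* randomized-shortest-path (RSP) net passage probabilities — the stochastic
  trajectory of an expanding crop between a pure random walk (theta = 0)
  and the deterministic least-cost path (theta -> inf);
* path overlap and path divergence — resistance-weighted summaries of how
  much two trajectories from a common origin share or split, predictors of
  pairwise genetic similarity/distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
from scipy.sparse.linalg import splu

from .geodesy import great_circle_km
from .raster import LAND_CODE, RasterGrid

#: net passage values below this are dropped from sparse trajectory matrices
NET_PASSAGE_FLOOR = 1e-12


def cost_matrix(landscape: sp.spmatrix) -> sp.csr_matrix:
    """Per-connection travel costs: reciprocal of conductance on the support."""
    c = landscape.tocsr().copy()
    c.data = 1.0 / c.data
    return c


def resistance(landscape: sp.spmatrix) -> sp.csr_matrix:
    """Resistance matrix R = 1/conductance, defined only on existing connections."""
    return cost_matrix(landscape)


def least_cost_distance(landscape: sp.spmatrix, origin: int, targets=None):
    """Least-cost distances from ``origin`` to ``targets`` (all cells if None).

    The cost of a path is the sum of reciprocal conductances of its
    connections; with per-km conductances this is a cost-distance in km
    multiples of resistance. Unreachable targets get ``inf``.
    """
    n = landscape.shape[0]
    if not 0 <= origin < n:
        raise ValueError("origin cell out of range")
    if landscape.tocsr()[origin].nnz == 0:
        raise ValueError("origin cell has no connections in the landscape")
    dist = dijkstra(cost_matrix(landscape), directed=False, indices=origin)
    if targets is None:
        return dist
    return dist[np.asarray(targets)]


@dataclass
class TrajectoryMatrix:
    """Net passage probabilities of one origin->destination RSP trajectory.

    ``net[i, j]`` is the expected net number of forward transitions over the
    connection (i, j) for unit flow from origin to destination; values lie
    in [0, 1] and satisfy flow conservation at intermediate cells.
    """

    origin: int
    dest: int
    theta: float
    net: sp.csr_matrix

    @property
    def n_cells(self) -> int:
        return self.net.shape[0]

    def total_passage_per_cell(self) -> np.ndarray:
        """Per-cell sum of incident net passage values (for raster export)."""
        return np.asarray(self.net.sum(axis=0)).ravel() + np.asarray(
            self.net.sum(axis=1)
        ).ravel()


def rsp_net_passage(
    landscape: sp.spmatrix, origin: int, dest: int, theta: float
) -> TrajectoryMatrix:
    """Randomized-shortest-path net passage probabilities from origin to dest.

    The reference random walk follows conductances, P_ref[i,j] = c_ij / sum_k
    c_ik; transition weights are Boltzmann-tilted by the per-step costs,
    W = P_ref o exp(-theta/c); the destination is made absorbing.  With
    Z = (I - W)^-1, the expected number of (i, j) passages is
    z[o,i] W[i,j] z[j,d] / z[o,d], and the net passage is the positive part
    of the asymmetry n_ij - n_ji.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    n = landscape.shape[0]
    if origin == dest:
        raise ValueError("origin and destination must differ")
    if not (0 <= origin < n and 0 <= dest < n):
        raise ValueError("origin/destination out of range")

    c = landscape.tocsr()
    deg = np.asarray(c.sum(axis=1)).ravel()
    if deg[origin] == 0 or deg[dest] == 0:
        raise ValueError("origin or destination has no connections")
    inv_deg = np.zeros(n)
    nz = deg > 0
    inv_deg[nz] = 1.0 / deg[nz]
    pref = sp.diags(inv_deg) @ c

    w = pref.tocoo()
    costs = 1.0 / np.asarray(c[w.row, w.col]).ravel()
    data = w.data * np.exp(-theta * costs)
    keep = w.row != dest  # absorbing destination: no transitions out
    w = sp.coo_matrix((data[keep], (w.row[keep], w.col[keep])), shape=(n, n)).tocsr()

    a = (sp.identity(n, format="csc") - w.tocsc())
    try:
        lu = splu(a)
    except RuntimeError as exc:
        raise ValueError(
            "I - W is singular; the walk cannot be absorbed at the destination"
        ) from exc
    e_o = np.zeros(n)
    e_o[origin] = 1.0
    e_d = np.zeros(n)
    e_d[dest] = 1.0
    z_row = lu.solve(e_o, trans="T")  # z[origin, :]
    z_col = lu.solve(e_d)  # z[:, dest]
    z_od = z_row[dest]
    if not np.isfinite(z_od) or z_od <= 0:
        raise ValueError(
            "destination unreachable from origin (z[origin, dest] = 0); "
            "theta may be too large for the cost scale, or the graph disconnected"
        )

    wc = w.tocoo()
    n_ij = z_row[wc.row] * wc.data * z_col[wc.col] / z_od
    passages = sp.coo_matrix((n_ij, (wc.row, wc.col)), shape=(n, n)).tocsr()
    net = (passages - passages.T).maximum(0).tocsr()
    net.data[net.data < NET_PASSAGE_FLOOR] = 0.0
    net.eliminate_zeros()
    return TrajectoryMatrix(origin=origin, dest=dest, theta=theta, net=net)


def _aligned_values(pa: TrajectoryMatrix, pb: TrajectoryMatrix, r: sp.spmatrix):
    if pa.origin != pb.origin:
        raise ValueError("trajectories must share the same origin")
    if pa.theta != pb.theta:
        raise ValueError("trajectories must share the same theta")
    if pa.n_cells != pb.n_cells or r.shape != pa.net.shape:
        raise ValueError("trajectories and resistance must share one landscape")
    support = (pa.net + pb.net).tocoo()
    rows, cols = support.row, support.col
    a = np.asarray(pa.net[rows, cols]).ravel()
    b = np.asarray(pb.net[rows, cols]).ravel()
    rv = np.asarray(r.tocsr()[rows, cols]).ravel()
    if np.any(rv <= 0):
        raise ValueError("net passage found on a connection absent from the landscape")
    return a, b, rv


def path_overlap(pa: TrajectoryMatrix, pb: TrajectoryMatrix, r: sp.spmatrix) -> float:
    """Resistance-weighted probability mass of joint passage of two trajectories.

    P_joint = Pa o Pb element-wise; overlap = sum(P_joint o R).
    """
    a, b, rv = _aligned_values(pa, pb, r)
    return float(np.sum(a * b * rv))


def path_divergence(pa: TrajectoryMatrix, pb: TrajectoryMatrix, r: sp.spmatrix) -> float:
    """Resistance-weighted mass of the divergent parts of two trajectories.

    On each connection, with hi = max(Pa, Pb) and lo = min(Pa, Pb), the
    probability that the more probable trajectory passes while the less
    probable one does not is d = hi * (1 - lo); the connection counts as
    divergent only where d exceeds lo.
    """
    a, b, rv = _aligned_values(pa, pb, r)
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    d = hi * (1.0 - lo)
    return float(np.sum(np.where(d > lo, d, 0.0) * rv))


def trajectory_cost(p: TrajectoryMatrix, r: sp.spmatrix) -> float:
    """Resistance-weighted length of one trajectory, sum(P o R).

    Converges to the least-cost distance as theta -> inf.
    """
    coo = p.net.tocoo()
    rv = np.asarray(r.tocsr()[coo.row, coo.col]).ravel()
    return float(np.sum(coo.data * rv))


def site_to_cell(
    grid: RasterGrid, lon: float, lat: float, land_code: float = LAND_CODE
):
    """Map a point to its grid cell; snap to the nearest land cell when the
    containing cell is water or nodata.

    Returns ``(cell_index, snapped)``.
    """
    index = grid.lonlat_to_index(lon, lat)
    land = grid.land_mask(land_code)
    if land[index]:
        return index, False
    if not land.any():
        raise ValueError("grid has no land cells to snap to")
    lons, lats = grid.all_centers()
    land_idx = np.flatnonzero(land)
    d = great_circle_km(lon, lat, lons[land_idx], lats[land_idx])
    return int(land_idx[int(np.argmin(d))]), True


def passage_raster(p: TrajectoryMatrix, grid: RasterGrid) -> RasterGrid:
    """Per-cell total passage of a trajectory as a raster (map export)."""
    if p.n_cells != grid.n_cells:
        raise ValueError("trajectory and grid sizes differ")
    return grid.like(p.total_passage_per_cell())
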