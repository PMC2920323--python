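"""Multi-criteria search for the crop origin and landscape parameters.

A candidate solution is (origin longitude, origin latitude, p1, p2).  Each
candidate is scored by two goodness-of-fit objectives to be maximized
simultaneously: R1 of the weighted tau-quantile regression of calibrated
radiocarbon ages on least-cost distance from the origin, and R1 of the
quantile regression of accession heterozygosity on the same distance.  The
search uses NSGA-II (non-dominated sorting, crowding distance, binary
tournament, SBX crossover, polynomial mutation) and returns the final
Pareto front.  p1 and p2 are searched on a log scale because their
plausible values span orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import least_cost_distance, site_to_cell
from .fitting import FitResult, quantile_fit, spatial_weights
from .landscape import LandscapeParams, assemble_landscape
from .raster import RasterGrid, distance_to_coast

#: objectives assigned to candidates whose origin cannot reach the data
INFEASIBLE = -np.inf


@dataclass
class ParetoSolution:
    """One non-dominated solution: origin, landscape parameters, objectives."""

    lon: float
    lat: float
    p1: float
    p2: float
    objectives: tuple

    @property
    def r1_age(self) -> float:
        return self.objectives[0]

    @property
    def r1_het(self) -> float:
        return self.objectives[1]


class DispersalEvaluator:
    """Scores (lon, lat, p1, p2) candidates against site ages and heterozygosity.

    ``sites`` needs columns lon, lat, cal_age_BP; ``accessions`` needs
    lon, lat, het.  Site observations are weighted by 1/(number of
    observations within ``weight_radius_km``); heterozygosity observations
    are unweighted.  Candidates whose origin is disconnected from more than
    half the sites get ``-inf`` objectives.
    """

    def __init__(
        self,
        grid: RasterGrid,
        sites: pd.DataFrame,
        accessions: pd.DataFrame,
        tau: float = 0.8,
        directions: int = 8,
        weight_radius_km: float = 100.0,
    ):
        self.grid = grid
        self.tau = tau
        self.directions = directions
        self.dist_to_coast = distance_to_coast(grid)
        self.sites = sites.reset_index(drop=True)
        self.accessions = accessions.reset_index(drop=True)
        self.site_cells = np.array(
            [site_to_cell(grid, r.lon, r.lat)[0] for r in self.sites.itertuples()]
        )
        self.accession_cells = np.array(
            [site_to_cell(grid, r.lon, r.lat)[0] for r in self.accessions.itertuples()]
        )
        self.site_weights = spatial_weights(
            self.sites["lon"], self.sites["lat"], weight_radius_km
        )
        self.ages = self.sites["cal_age_BP"].to_numpy(float)
        self.het = self.accessions["het"].to_numpy(float)

    def landscape_for(self, p1: float, p2: float):
        params = LandscapeParams(p1=p1, p2=p2, directions=self.directions)
        return assemble_landscape(self.grid, params, self.dist_to_coast)

    def origin_cell(self, lon: float, lat: float) -> int:
        cell, _ = site_to_cell(self.grid, lon, lat)
        return cell

    def fits(self, lon, lat, p1, p2) -> tuple[FitResult, FitResult] | None:
        """Both quantile fits for a candidate, or None if infeasible."""
        try:
            landscape = self.landscape_for(p1, p2)
            origin = self.origin_cell(lon, lat)
            dist = least_cost_distance(landscape, origin)
        except ValueError:
            return None
        d_sites = dist[self.site_cells]
        d_acc = dist[self.accession_cells]
        reachable = np.isfinite(d_sites)
        if reachable.mean() <= 0.5:
            return None
        ok_acc = np.isfinite(d_acc)
        if ok_acc.sum() < 3:
            return None
        age_fit = quantile_fit(
            d_sites[reachable],
            self.ages[reachable],
            tau=self.tau,
            weights=self.site_weights[reachable],
        )
        het_fit = quantile_fit(d_acc[ok_acc], self.het[ok_acc], tau=self.tau)
        return age_fit, het_fit

    def __call__(self, lon, lat, p1, p2) -> tuple:
        fits = self.fits(lon, lat, p1, p2)
        if fits is None:
            return (INFEASIBLE, INFEASIBLE)
        return (fits[0].goodness, fits[1].goodness)


# -- NSGA-II ------------------------------------------------------------

def _dominates(fa: np.ndarray, fb: np.ndarray) -> bool:
    """Maximization dominance: fa >= fb everywhere and > somewhere."""
    return bool(np.all(fa >= fb) and np.any(fa > fb))


def fast_non_dominated_sort(objs: np.ndarray) -> list[np.ndarray]:
    """Partition rows of a (n, m) objective array into Pareto fronts."""
    n = objs.shape[0]
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for a in range(n):
        for b in range(a + 1, n):
            if _dominates(objs[a], objs[b]):
                dominated_by[a].append(b)
                dom_count[b] += 1
            elif _dominates(objs[b], objs[a]):
                dominated_by[b].append(a)
                dom_count[a] += 1
    fronts = []
    current = np.flatnonzero(dom_count == 0)
    while current.size:
        fronts.append(current)
        nxt = []
        for a in current:
            for b in dominated_by[a]:
                dom_count[b] -= 1
                if dom_count[b] == 0:
                    nxt.append(b)
        current = np.array(sorted(set(nxt)), dtype=int)
    return fronts

def crowding_distance(objs: np.ndarray) -> np.ndarray:
    n, m = objs.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    finite = np.where(np.isfinite(objs), objs, -1e30)
    for k in range(m):
        order = np.argsort(finite[:, k], kind="stable")
        lo, hi = finite[order[0], k], finite[order[-1], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        if hi > lo:
            gaps = (finite[order[2:], k] - finite[order[:-2], k]) / (hi - lo)
            dist[order[1:-1]] += gaps
    return dist


def _sbx_crossover(pa, pb, bounds, rng, eta=15.0, prob=0.9):
    """Simulated binary crossover, per-variable."""
    child_a, child_b = pa.copy(), pb.copy()
    if rng.random() > prob:
        return child_a, child_b
    for k in range(len(pa)):
        if rng.random() > 0.5 or abs(pa[k] - pb[k]) < 1e-14:
            continue
        x1, x2 = sorted((pa[k], pb[k]))
        u = rng.random()
        beta = (2 * u) ** (1 / (eta + 1)) if u <= 0.5 else (1 / (2 * (1 - u))) ** (1 / (eta + 1))
        c1 = 0.5 * ((x1 + x2) - beta * (x2 - x1))
        c2 = 0.5 * ((x1 + x2) + beta * (x2 - x1))
        lo, hi = bounds[k]
        child_a[k] = np.clip(c1, lo, hi)
        child_b[k] = np.clip(c2, lo, hi)
    return child_a, child_b


def _poly_mutation(x, bounds, rng, eta=20.0, prob=None):
    """Polynomial mutation, per-variable probability 1/n_var by default."""
    x = x.copy()
    if prob is None:
        prob = 1.0 / len(x)
    for k in range(len(x)):
        if rng.random() >= prob:
            continue
        lo, hi = bounds[k]
        span = hi - lo
        if span <= 0:
            continue
        u = rng.random()
        if u < 0.5:
            delta = (2 * u) ** (1 / (eta + 1)) - 1
        else:
            delta = 1 - (2 * (1 - u)) ** (1 / (eta + 1))
        x[k] = np.clip(x[k] + delta * span, lo, hi)
    return x


def nsga2(
    evaluate,
    bounds,
    pop_size: int = 200,
    generations: int = 200,
    seed: int | None = None,
    history: list | None = None,
):
    """NSGA-II maximizing a vector objective over box-bounded real genes.

    ``evaluate(x) -> tuple`` of objectives (larger is better; ``-inf`` marks
    infeasible candidates, which are dominated by construction).  Returns
    ``(X, F)``: the decision vectors and objectives of the final
    non-dominated, feasible set.  Deterministic under a fixed seed.  If
    ``history`` is a list, the hypervolume of the feasible front (reference
    point = 0) is appended each generation.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or np.any(bounds[:, 0] > bounds[:, 1]):
        raise ValueError("bounds must be an (n_var, 2) array with lo <= hi")
    n_var = bounds.shape[0]
    rng = np.random.default_rng(seed)

    pop = rng.uniform(bounds[:, 0], bounds[:, 1], size=(pop_size, n_var))
    objs = np.array([evaluate(x) for x in pop], dtype=float)

    def rank_and_crowd(f):
        fronts = fast_non_dominated_sort(f)
        rank = np.empty(f.shape[0], dtype=int)
        crowd = np.empty(f.shape[0])
        for r, idx in enumerate(fronts):
            rank[idx] = r
            crowd[idx] = crowding_distance(f[idx])
        return rank, crowd, fronts

    rank, crowd, _ = rank_and_crowd(objs)

    def tournament():
        a, b = rng.integers(pop_size), rng.integers(pop_size)
        if rank[a] < rank[b] or (rank[a] == rank[b] and crowd[a] > crowd[b]):
            return a
        return b

    for _ in range(generations):
        children = []
        while len(children) < pop_size:
            pa, pb = pop[tournament()], pop[tournament()]
            ca, cb = _sbx_crossover(pa, pb, bounds, rng)
            children.append(_poly_mutation(ca, bounds, rng))
            if len(children) < pop_size:
                children.append(_poly_mutation(cb, bounds, rng))
        child_objs = np.array([evaluate(x) for x in children], dtype=float)
        pop = np.vstack([pop, children])
        objs = np.vstack([objs, child_objs])

        rank_all, crowd_all, fronts = rank_and_crowd(objs)
        keep: list[int] = []
        for idx in fronts:
            if len(keep) + len(idx) <= pop_size:
                keep.extend(idx.tolist())
            else:
                by_crowd = idx[np.argsort(-crowd_all[idx], kind="stable")]
                keep.extend(by_crowd[: pop_size - len(keep)].tolist())
                break
        keep_arr = np.array(keep)
        pop, objs = pop[keep_arr], objs[keep_arr]
        rank, crowd, _ = rank_and_crowd(objs)
        if history is not None:
            feas = np.all(np.isfinite(objs), axis=1)
            front0 = objs[(rank == 0) & feas]
            history.append(hypervolume_2d(front0) if front0.size else 0.0)

    feasible = np.all(np.isfinite(objs), axis=1)
    pop, objs = pop[feasible], objs[feasible]
    if pop.shape[0] == 0:
        return pop, objs
    fronts = fast_non_dominated_sort(objs)
    idx = fronts[0]
    # deduplicate identical decision vectors
    _, uniq = np.unique(np.round(pop[idx], 12), axis=0, return_index=True)
    idx = idx[np.sort(uniq)]
    return pop[idx], objs[idx]


def hypervolume_2d(front: np.ndarray, ref=(0.0, 0.0)) -> float:
    """Dominated hypervolume of a 2-D maximization front w.r.t. a reference point."""
    f = np.asarray(front, dtype=float)
    if f.size == 0:
        return 0.0
    f = f[np.all(f >= np.asarray(ref), axis=1)]
    if f.size == 0:
        return 0.0
    order = np.argsort(-f[:, 0], kind="stable")
    f = f[order]
    hv = 0.0
    best_y = ref[1]
    for x, y in f:
        if y > best_y:
            hv += (x - ref[0]) * (y - best_y)
            best_y = y
    return hv


def optimize_dispersal(
    evaluator: DispersalEvaluator,
    lon_bounds=None,
    lat_bounds=None,
    p1_bounds=(1e-3, 1e2),
    p2_bounds=(1e2, 1e4),
    pop_size: int = 200,
    generations: int = 200,
    seed: int | None = None,
    history: list | None = None,
) -> list[ParetoSolution]:
    """Run the NSGA-II search over (lon, lat, log10 p1, log10 p2).

    Origin bounds default to the grid's bounding box; p1/p2 are searched on
    a log10 scale.  Returns the Pareto front as ``ParetoSolution`` records.
    """
    grid = evaluator.grid
    if lon_bounds is None:
        lon_bounds = (grid.xllcorner, grid.xright)
    if lat_bounds is None:
        lat_bounds = (grid.yllcorner, grid.ytop)
    bounds = np.array(
        [lon_bounds, lat_bounds, np.log10(p1_bounds), np.log10(p2_bounds)]
    )

    def evaluate(x):
        lon, lat, lp1, lp2 = x
        eps = 1e-9  # keep strictly inside the half-open grid bounds
        lon = min(max(lon, grid.xllcorner), grid.xright - eps)
        lat = min(max(lat, grid.yllcorner + eps), grid.ytop)
        return evaluator(lon, lat, 10.0 ** lp1, 10.0 ** lp2)

    xs, fs = nsga2(evaluate, bounds, pop_size, generations, seed, history)
    solutions = []
    for x, f in zip(xs, fs):
        lon, lat, lp1, lp2 = x
        cell = evaluator.origin_cell(
            min(max(lon, grid.xllcorner), grid.xright - 1e-9),
            min(max(lat, grid.yllcorner + 1e-9), grid.ytop),
        )
        clon, clat = grid.cell_center(cell)
        solutions.append(
            ParetoSolution(lon=clon, lat=clat, p1=10.0 ** lp1, p2=10.0 ** lp2,
                           objectives=tuple(f))
        )
    return solutions


def front_select(front: list[ParetoSolution], k: int) -> list[ParetoSolution]:
    """k representative solutions spread along the front by objective-space
    arc length (always includes both extremes)."""
    if not front:
        raise ValueError("empty front")
    if k >= len(front):
        return list(front)
    if k < 2:
        raise ValueError("k must be at least 2")
    ordered = sorted(front, key=lambda s: (s.objectives[0], s.objectives[1]))
    pts = np.array([s.objectives for s in ordered], dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], k)
    chosen = []
    for t in targets:
        i = int(np.argmin(np.abs(arc - t)))
        if i not in chosen:
            chosen.append(i)
    # top up if rounding collapsed targets onto the same solution
    for i in range(len(ordered)):
        if len(chosen) >= k:
            break
        if i not in chosen:
            chosen.append(i)
    return [ordered[i] for i in sorted(chosen)]


def front_to_frame(front: list[ParetoSolution]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lon": s.lon,
                "lat": s.lat,
                "p1": s.p1,
                "p2": s.p2,
                "r1_age": s.objectives[0],
                "r1_het": s.objectives[1],
            }
            for s in front
        ]
    )
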