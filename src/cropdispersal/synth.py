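"""Synthetic landscapes, arrival ages, and genotypes.

The generators emulate the statistical structure the inference method
assumes: a landmass with islands and a coastline, crop arrival ages that
decrease linearly with least-cost distance from the origin (observed ages
postdating arrival by one-sided noise, since a site can only record a crop
at or after its arrival), and genotypes produced by serial founder events
along dispersal routes so that heterozygosity declines with cost-distance
and genetic distance grows when routes diverge early.

Founder events are applied along the least-cost route tree (not the full
RSP ensemble): accessions whose routes share a segment share that segment's
drift history, which is what makes path overlap informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .distances import cost_matrix
from .genetics import GenotypeTable
from .landscape import LandscapeParams, assemble_landscape
from .raster import RasterGrid, distance_to_coast, write_ascii_grid


@dataclass
class SyntheticScenario:
    """Study conditions of one synthetic experiment.

    Counts follow the real maize application (193 accessions x 99 SSR loci);
    the grid, origin, and landscape parameters are free choices of the
    experiment. ``speed`` is km of cost-distance per year; ``age_noise`` the
    mean of the one-sided exponential recording delay in years;
    ``bottleneck`` the founder-event rate per km of route.
    """

    n_rows: int = 40
    n_cols: int = 40
    cellsize: float = 0.5
    xllcorner: float = -100.0
    yllcorner: float = -5.0
    land_fraction: float = 0.65
    smoothing: float = 3.0
    true_origin_lonlat: tuple | None = None
    true_p1: float = 0.5
    true_p2: float = 1000.0
    directions: int = 8
    age0: float = 9000.0
    speed: float = 1.0
    age_noise: float = 300.0
    bottleneck: float = 0.01
    founder_size: int = 10
    n_sites: int = 200
    n_accessions: int = 193
    n_loci: int = 99
    alleles_per_locus: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_rows", "n_cols", "n_sites", "n_accessions", "n_loci",
                     "alleles_per_locus", "founder_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.age_noise < 0 or self.bottleneck < 0:
            raise ValueError("noise and bottleneck intensities must be >= 0")


def make_landmass(spec: SyntheticScenario, seed: int | None = None) -> RasterGrid:
    """Random landmass raster: a smoothed Gaussian field thresholded at the
    requested land fraction (land = 1, water = 0).

    The largest connected land component is the mainland; smaller components
    are islands. A land fraction of 0 or 1 beyond rounding is rejected,
    except the degenerate all-land request ``land_fraction == 1.0`` which is
    honoured exactly.
    """
    if seed is None:
        seed = spec.seed
    if spec.land_fraction >= 1.0:
        if spec.land_fraction > 1.0:
            raise ValueError("land fraction must be <= 1")
        values = np.ones((spec.n_rows, spec.n_cols))
        return RasterGrid(values, spec.xllcorner, spec.yllcorner, spec.cellsize)
    if spec.land_fraction <= 0.0:
        raise ValueError("land fraction must be positive")
    rng = np.random.default_rng(seed)
    f = ndi.gaussian_filter(
        rng.standard_normal((spec.n_rows, spec.n_cols)), spec.smoothing, mode="wrap"
    )
    threshold = np.quantile(f, 1.0 - spec.land_fraction)
    land = f >= threshold
    return RasterGrid(
        land.astype(float), spec.xllcorner, spec.yllcorner, spec.cellsize
    )


def mainland_cells(grid: RasterGrid) -> np.ndarray:
    """Flat indices of the largest connected (queen's case) land component."""
    land = grid.land_mask().reshape(grid.n_rows, grid.n_cols)
    labels, n = ndi.label(land, structure=np.ones((3, 3)))
    if n == 0:
        raise ValueError("grid has no land")
    sizes = ndi.sum_labels(land, labels, index=np.arange(1, n + 1))
    main = 1 + int(np.argmax(sizes))
    return np.flatnonzero((labels == main).ravel())


def _scenario_landscape(spec: SyntheticScenario, grid: RasterGrid):
    params = LandscapeParams(spec.true_p1, spec.true_p2, spec.directions)
    dtc = distance_to_coast(grid) if grid.water_mask().any() else None
    return assemble_landscape(grid, params, dtc)


def _pick_origin(spec: SyntheticScenario, grid: RasterGrid, rng) -> int:
    if spec.true_origin_lonlat is not None:
        from .distances import site_to_cell

        cell, _ = site_to_cell(grid, *spec.true_origin_lonlat)
        return cell
    return int(rng.choice(mainland_cells(grid)))


def simulate_ages(
    landscape: sp.spmatrix,
    grid: RasterGrid,
    origin: int,
    site_cells: np.ndarray,
    speed: float,
    noise: float,
    age0: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """Observed calibrated ages BP at sites: arrival age minus exponential delay.

    arrival(s) = age0 - costdist(origin, s)/speed; the observed age is
    arrival - Exponential(mean=noise) (one-sided: a site records the crop at
    or after its arrival). Unreachable sites are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    dist = dijkstra(cost_matrix(landscape), directed=False, indices=origin)
    d = dist[site_cells]
    reachable = np.isfinite(d)
    if not reachable.all():
        import warnings

        warnings.warn(f"dropped {int((~reachable).sum())} unreachable sites")
    cells = np.asarray(site_cells)[reachable]
    d = d[reachable]
    arrival = age0 - d / speed
    delay = rng.exponential(noise, size=d.size) if noise > 0 else np.zeros(d.size)
    lons, lats = grid.cell_center(cells)
    return pd.DataFrame(
        {
            "id": [f"site{k + 1}" for k in range(d.size)],
            "lon": lons,
            "lat": lats,
            "cal_age_BP": arrival - delay,
            "cost_distance": d,
        }
    )


def _route_tree(landscape: sp.spmatrix, origin: int):
    """Least-cost predecessors and per-cell route costs from the origin."""
    dist, pred = dijkstra(
        cost_matrix(landscape), directed=False, indices=origin, return_predecessors=True
    )
    return dist, pred


def simulate_genotypes(
    landscape: sp.spmatrix,
    grid: RasterGrid,
    origin: int,
    accession_cells: np.ndarray,
    bottleneck: float,
    n_loci: int,
    alleles_per_locus: int = 8,
    founder_size: int = 10,
    seed: int | None = None,
) -> GenotypeTable:
    """Serial-founder genotype simulation along least-cost routes.

    Founder allele frequencies per locus are Dirichlet(1); walking the
    least-cost route tree away from the origin, every edge applies
    ``round(bottleneck * edge_cost)`` (stochastically rounded) binomial
    founder events, each resampling frequencies from a multinomial draw of
    2 * founder_size allele copies. Cells reached through a shared route
    segment share that segment's drift history. Two alleles per locus are
    then drawn per accession from its cell's frequencies.
    """
    if n_loci < 1:
        raise ValueError("need at least one locus")
    rng = np.random.default_rng(seed)
    dist, pred = _route_tree(landscape, origin)
    cells = np.asarray(accession_cells)
    if np.any(~np.isfinite(dist[cells])):
        raise ValueError("some accession cells are unreachable from the origin")

    base = rng.dirichlet(np.ones(alleles_per_locus), size=n_loci)  # (L, A)
    freqs: dict[int, np.ndarray] = {int(origin): base}
    copies = 2 * founder_size

    def frequencies_at(cell: int) -> np.ndarray:
        """Frequencies at a cell, simulating missing ancestors on the way."""
        path = []
        c = int(cell)
        while c not in freqs:
            path.append(c)
            c = int(pred[c])
            if c < 0:
                raise ValueError(f"cell {cell} has no route from the origin")
        for node in reversed(path):
            parent = int(pred[node])
            f = freqs[parent]
            edge_cost = dist[node] - dist[parent]
            expected = bottleneck * edge_cost
            n_events = int(np.floor(expected))
            if rng.random() < expected - n_events:
                n_events += 1
            for _ in range(n_events):
                counts = np.vstack([rng.multinomial(copies, p) for p in f])
                f = counts / copies
                # a locus fixed for a lost allele stays fixed; renormalize guards 0-rows
                f = f / f.sum(axis=1, keepdims=True)
            freqs[node] = f
        return freqs[int(cell)]

    n = cells.size
    alleles = np.empty((n, n_loci, 2), dtype=object)
    for i, cell in enumerate(cells):
        f = frequencies_at(int(cell))
        for k in range(n_loci):
            draws = rng.choice(alleles_per_locus, size=2, p=f[k])
            alleles[i, k, 0] = f"a{draws[0]}"
            alleles[i, k, 1] = f"a{draws[1]}"
    lons, lats = grid.cell_center(cells)
    return GenotypeTable(
        ids=np.array([f"acc{k + 1}" for k in range(n)], dtype=object),
        lons=lons,
        lats=lats,
        alleles=alleles,
    )


@dataclass
class Scenario:
    """A fully generated synthetic study: inputs plus ground truth."""

    spec: SyntheticScenario
    grid: RasterGrid
    landscape: sp.spmatrix
    origin_cell: int
    sites: pd.DataFrame
    genotypes: GenotypeTable
    truth: dict = field(default_factory=dict)


def generate_scenario(spec: SyntheticScenario, seed: int | None = None) -> Scenario:
    """Generate grid, sites, and genotypes for one scenario (deterministic per seed)."""
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    grid = make_landmass(spec, seed)
    landscape = _scenario_landscape(spec, grid)
    origin = _pick_origin(spec, grid, rng)
    mainland = mainland_cells(grid)
    reach = dijkstra(cost_matrix(landscape), directed=False, indices=origin)
    usable = mainland[np.isfinite(reach[mainland])]
    site_cells = rng.choice(usable, size=min(spec.n_sites, usable.size), replace=True)
    acc_cells = rng.choice(usable, size=min(spec.n_accessions, usable.size), replace=True)
    sites = simulate_ages(
        landscape, grid, origin, site_cells, spec.speed, spec.age_noise, spec.age0,
        seed=rng.integers(2**31),
    )
    genotypes = simulate_genotypes(
        landscape, grid, origin, acc_cells, spec.bottleneck, spec.n_loci,
        spec.alleles_per_locus, spec.founder_size, seed=rng.integers(2**31),
    )
    olon, olat = grid.cell_center(origin)
    truth = {
        "origin_cell": int(origin),
        "origin_lon": float(olon),
        "origin_lat": float(olat),
        "p1": spec.true_p1,
        "p2": spec.true_p2,
        "speed": spec.speed,
        "age0": spec.age0,
    }
    return Scenario(spec, grid, landscape, origin, sites, genotypes, truth)


def write_scenario(scenario: Scenario, outdir) -> None:
    """Emit a scenario directory: grid.asc, sites.csv, genotypes.csv, truth.json."""
    import json

    from .genetics import genotype_table_to_wide

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(scenario.grid, outdir / "grid.asc")
    scenario.sites.drop(columns=["cost_distance"]).to_csv(
        outdir / "sites.csv", index=False
    )
    genotype_table_to_wide(scenario.genotypes).to_csv(
        outdir / "genotypes.csv", index=False
    )
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(scenario.truth, fh, indent=2)
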