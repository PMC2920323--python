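"""End-to-end analysis workflows combining the package's modules.

These drive the complete inference on a dataset (real or synthetic):
evaluate fixed parameter solutions, run the multi-criteria search, and
score trajectory overlap/divergence against genetic distances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .distances import rsp_net_passage, resistance, site_to_cell
from .fitting import FitResult, distance_regression, ols_matrix_regression
from .genetics import GenotypeTable, distance_matrix, heterozygosity
from .geodesy import great_circle_matrix
from .optimize import DispersalEvaluator, optimize_dispersal
from .synth import Scenario, SyntheticScenario, generate_scenario


def het_frame(genotypes: GenotypeTable) -> pd.DataFrame:
    """Per-accession heterozygosity table (id, lon, lat, het)."""
    return pd.DataFrame(
        {
            "id": genotypes.ids,
            "lon": genotypes.lons,
            "lat": genotypes.lats,
            "het": heterozygosity(genotypes),
        }
    )


def trajectory_metric_matrices(
    landscape,
    grid,
    origin_cell: int,
    lons,
    lats,
    theta: float,
):
    """Pairwise path-overlap and path-divergence matrices for sample points.

    One RSP trajectory is solved per distinct destination cell; points whose
    cell equals the origin contribute zero-valued rows.
    """
    cells = np.array([site_to_cell(grid, lo, la)[0] for lo, la in zip(lons, lats)])
    r = resistance(landscape)
    trajs = {}
    for c in np.unique(cells):
        if int(c) != int(origin_cell):
            trajs[int(c)] = rsp_net_passage(landscape, int(origin_cell), int(c), theta)
    n = cells.size
    overlap = np.zeros((n, n))
    divergence = np.zeros((n, n))
    from .distances import path_divergence, path_overlap

    for a in range(n):
        ta = trajs.get(int(cells[a]))
        if ta is None:
            continue
        for b in range(a + 1, n):
            tb = trajs.get(int(cells[b]))
            if tb is None:
                continue
            overlap[a, b] = overlap[b, a] = path_overlap(ta, tb, r)
            divergence[a, b] = divergence[b, a] = path_divergence(ta, tb, r)
    return overlap, divergence


def genetic_distance_regressions(
    scenario: Scenario,
    theta: float = 0.1,
    n_accessions: int = 40,
    n_perm: int = 199,
    seed: int | None = None,
) -> dict:
    """Score trajectory metrics and the isolation-by-distance baseline
    against the scenario's genetic distances (on an accession subsample)."""
    rng = np.random.default_rng(seed)
    g = scenario.genotypes
    size = min(n_accessions, g.n_accessions)
    idx = rng.choice(g.n_accessions, size=size, replace=False)
    gd = distance_matrix(g)[np.ix_(idx, idx)]
    overlap, divergence = trajectory_metric_matrices(
        scenario.landscape,
        scenario.grid,
        scenario.origin_cell,
        g.lons[idx],
        g.lats[idx],
        theta,
    )
    traj_fit = distance_regression(gd, overlap, divergence, n_perm=n_perm, seed=seed)
    ibd_fit = ols_matrix_regression(
        gd, great_circle_matrix(g.lons[idx], g.lats[idx]), n_perm=0
    )
    return {"trajectory": traj_fit, "ibd": ibd_fit, "n_accessions": size}


def origin_errors_cells(front, grid, true_origin_cell: int) -> np.ndarray:
    """Chebyshev distance in grid cells between each front origin and truth."""
    tr, tc = grid.index_to_rowcol(true_origin_cell)
    errors = []
    for s in front:
        cell = grid.lonlat_to_index(s.lon, s.lat)
        r, c = grid.index_to_rowcol(cell)
        errors.append(max(abs(int(r) - int(tr)), abs(int(c) - int(tc))))
    return np.array(errors)


def recovery_study(
    seed: int,
    spec: SyntheticScenario | None = None,
    pop_size: int = 60,
    generations: int = 40,
) -> dict:
    """Full parameter-recovery experiment on one synthetic scenario.

    Generates the scenario, evaluates the true parameters, runs the NSGA-II
    search, and reports origin errors plus the zero-noise consistency checks.
    """
    if spec is None:
        spec = SyntheticScenario(seed=seed)
    scenario = generate_scenario(spec, seed)
    evaluator = DispersalEvaluator(
        scenario.grid, scenario.sites, het_frame(scenario.genotypes)
    )
    truth_fits = evaluator.fits(
        scenario.truth["origin_lon"],
        scenario.truth["origin_lat"],
        scenario.truth["p1"],
        scenario.truth["p2"],
    )
    front = optimize_dispersal(
        evaluator, pop_size=pop_size, generations=generations, seed=seed
    )
    errors = origin_errors_cells(front, scenario.grid, scenario.origin_cell)
    return {
        "scenario": scenario,
        "evaluator": evaluator,
        "front": front,
        "origin_errors": errors,
        "truth_fits": truth_fits,
    }


def evaluate_solution(
    grid,
    sites: pd.DataFrame,
    genotypes: GenotypeTable,
    lon: float,
    lat: float,
    p1: float,
    p2: float,
    tau: float = 0.8,
) -> tuple[FitResult, FitResult]:
    """Quantile fits (age, heterozygosity) for one fixed parameter solution."""
    evaluator = DispersalEvaluator(grid, sites, het_frame(genotypes), tau=tau)
    fits = evaluator.fits(lon, lat, p1, p2)
    if fits is None:
        raise ValueError("solution is infeasible on this dataset")
    return fits
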