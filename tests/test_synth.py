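import numpy as np
import pytest
from scipy.stats import spearmanr

import cropdispersal as cd
from cropdispersal.distances import cost_matrix
from cropdispersal.synth import mainland_cells
from scipy.sparse.csgraph import dijkstra


class TestMakeLandmass:
    def test_requested_fraction_achieved(self):
        spec = cd.SyntheticScenario(n_rows=50, n_cols=50, land_fraction=0.4, seed=1)
        grid = cd.make_landmass(spec)
        assert grid.land_mask().mean() == pytest.approx(0.4, abs=0.02)

    def test_full_land_fraction_gives_all_land(self):
        spec = cd.SyntheticScenario(land_fraction=1.0)
        grid = cd.make_landmass(spec)
        assert grid.land_mask().all()

    @pytest.mark.parametrize("fraction", [0.0, -0.2, 1.5])
    def test_degenerate_fractions_rejected(self, fraction):
        spec = cd.SyntheticScenario(land_fraction=fraction)
        with pytest.raises(ValueError):
            cd.make_landmass(spec)

    def test_same_seed_identical_grid(self):
        spec = cd.SyntheticScenario(n_rows=30, n_cols=30, seed=9)
        g1 = cd.make_landmass(spec)
        g2 = cd.make_landmass(spec)
        np.testing.assert_array_equal(g1.values, g2.values)

    def test_has_a_mainland_component(self):
        spec = cd.SyntheticScenario(n_rows=40, n_cols=40, seed=2)
        grid = cd.make_landmass(spec)
        mainland = mainland_cells(grid)
        assert mainland.size >= 0.3 * grid.land_mask().sum()


@pytest.fixture(scope="module")
def age_setup():
    spec = cd.SyntheticScenario(n_rows=25, n_cols=25, seed=6)
    grid = cd.make_landmass(spec)
    landscape = cd.assemble_landscape(
        grid, cd.LandscapeParams(spec.true_p1, spec.true_p2)
    )
    mainland = mainland_cells(grid)
    origin = int(mainland[len(mainland) // 2])
    return spec, grid, landscape, mainland, origin


class TestSimulateAges:

    def test_zero_noise_exactly_linear_with_unit_quantile_fit(self, age_setup):
        spec, grid, landscape, mainland, origin = age_setup
        sites = cd.simulate_ages(
            landscape, grid, origin, mainland, speed=1.3, noise=0.0,
            age0=9000.0, seed=0,
        )
        fit = cd.quantile_fit(sites["cost_distance"], sites["cal_age_BP"], tau=0.8)
        assert fit.goodness == pytest.approx(1.0, abs=1e-9)
        assert fit.slope == pytest.approx(-1.0 / 1.3, rel=1e-9)
        assert fit.intercept == pytest.approx(9000.0, abs=1e-6)

    def test_origin_site_records_age0(self, age_setup):
        spec, grid, landscape, mainland, origin = age_setup
        sites = cd.simulate_ages(
            landscape, grid, origin, np.array([origin]), speed=1.0, noise=0.0,
            age0=7777.0, seed=0,
        )
        assert sites["cal_age_BP"].iloc[0] == pytest.approx(7777.0)

    def test_exponential_noise_slope_recovered_within_ten_percent(self, age_setup):
        spec, grid, landscape, mainland, origin = age_setup
        rng = np.random.default_rng(0)
        cells = rng.choice(mainland, size=500, replace=True)
        sites = cd.simulate_ages(
            landscape, grid, origin, cells, speed=1.0, noise=250.0,
            age0=9000.0, seed=1,
        )
        fit = cd.quantile_fit(sites["cost_distance"], sites["cal_age_BP"], tau=0.8)
        assert fit.slope == pytest.approx(-1.0, rel=0.1)

    def test_unreachable_sites_dropped_with_warning(self):
        values = np.array([[1.0, 1.0, 0.0, 1.0]])
        grid = cd.RasterGrid(values, 0.0, 0.0, 0.5)
        landscape = cd.assemble_landscape(grid, cd.LandscapeParams(0.0, 100.0))
        with pytest.warns(UserWarning, match="unreachable"):
            sites = cd.simulate_ages(
                landscape, grid, 0, np.array([1, 3]), speed=1.0, noise=0.0,
                age0=5000.0, seed=0,
            )
        assert len(sites) == 1


@pytest.fixture(scope="module")
def geno_setup():
    spec = cd.SyntheticScenario(n_rows=25, n_cols=25, seed=8)
    grid = cd.make_landmass(spec)
    landscape = cd.assemble_landscape(
        grid, cd.LandscapeParams(spec.true_p1, spec.true_p2)
    )
    mainland = mainland_cells(grid)
    origin = int(mainland[0])
    dist = dijkstra(cost_matrix(landscape), directed=False, indices=origin)
    usable = mainland[np.isfinite(dist[mainland])]
    rng = np.random.default_rng(1)
    cells = rng.choice(usable, size=100, replace=True)
    return grid, landscape, origin, cells, dist


class TestSimulateGenotypes:

    def test_zero_bottleneck_keeps_heterozygosity_flat(self, geno_setup):
        grid, landscape, origin, cells, dist = geno_setup
        table = cd.simulate_genotypes(
            landscape, grid, origin, cells, bottleneck=0.0, n_loci=60, seed=2
        )
        het = cd.heterozygosity(table)
        rho, p = spearmanr(het, dist[cells])
        assert p > 0.01  # no drift, no cline

    def test_strong_bottleneck_creates_declining_cline(self, geno_setup):
        grid, landscape, origin, cells, dist = geno_setup
        table = cd.simulate_genotypes(
            landscape, grid, origin, cells, bottleneck=0.02, n_loci=60, seed=3
        )
        het = cd.heterozygosity(table)
        rho, p = spearmanr(het, dist[cells])
        assert rho < 0
        assert p < 0.001

    def test_shared_routes_are_genetically_closer_than_divergent_routes(self, geno_setup):
        """Two accessions at the same cell (fully shared route) should on
        average be closer than two equidistant accessions whose routes split
        at the origin."""
        grid, landscape, origin, cells, dist = geno_setup
        finite = np.flatnonzero(np.isfinite(dist))
        order = np.argsort(dist[finite])
        # two distinct far cells with similar cost-distance
        far = finite[order[-40:]]
        lon0, lat0 = grid.cell_center(origin)
        lons, lats = grid.all_centers()
        # pick the pair of far cells with the largest angular separation as
        # seen from the origin (divergent routes), and one single far cell
        best_pair, best_sep = None, -1.0
        for a in far[:20]:
            for b in far[:20]:
                sep = cd.great_circle_km(lons[a], lats[a], lons[b], lats[b])
                if sep > best_sep and abs(dist[a] - dist[b]) < 0.1 * dist[a]:
                    best_pair, best_sep = (a, b), sep
        a, b = best_pair
        same, split = [], []
        for rep in range(12):
            table = cd.simulate_genotypes(
                landscape, grid, origin, np.array([a, a, b]),
                bottleneck=0.02, n_loci=60, seed=100 + rep,
            )
            m = cd.distance_matrix(table)
            same.append(m[0, 1])  # identical routes (co-located accessions)
            split.append(m[0, 2])  # divergent routes
        assert np.mean(same) < np.mean(split)

    def test_deterministic_under_seed(self, geno_setup):
        grid, landscape, origin, cells, dist = geno_setup
        t1 = cd.simulate_genotypes(
            landscape, grid, origin, cells[:10], bottleneck=0.01, n_loci=10, seed=5
        )
        t2 = cd.simulate_genotypes(
            landscape, grid, origin, cells[:10], bottleneck=0.01, n_loci=10, seed=5
        )
        assert np.array_equal(t1.alleles, t2.alleles)

    def test_zero_loci_rejected(self, geno_setup):
        grid, landscape, origin, cells, dist = geno_setup
        with pytest.raises(ValueError):
            cd.simulate_genotypes(
                landscape, grid, origin, cells[:5], bottleneck=0.01, n_loci=0
            )


class TestScenario:
    def test_generate_scenario_deterministic(self):
        spec = cd.SyntheticScenario(
            n_rows=15, n_cols=15, n_sites=20, n_accessions=10, n_loci=8, seed=4
        )
        a = cd.generate_scenario(spec)
        b = cd.generate_scenario(spec)
        assert a.origin_cell == b.origin_cell
        np.testing.assert_array_equal(a.grid.values, b.grid.values)
        np.testing.assert_allclose(a.sites["cal_age_BP"], b.sites["cal_age_BP"])
        assert np.array_equal(a.genotypes.alleles, b.genotypes.alleles)

    def test_scenario_roundtrip_through_files(self, tmp_path):
        from cropdispersal.io import read_genotypes, read_sites
        from cropdispersal.synth import write_scenario

        spec = cd.SyntheticScenario(
            n_rows=15, n_cols=15, n_sites=20, n_accessions=10, n_loci=8, seed=4
        )
        sc = cd.generate_scenario(spec)
        write_scenario(sc, tmp_path)
        grid = cd.read_ascii_grid(tmp_path / "grid.asc")
        np.testing.assert_array_equal(grid.values, sc.grid.values)
        sites = read_sites(tmp_path / "sites.csv")
        np.testing.assert_allclose(sites["cal_age_BP"], sc.sites["cal_age_BP"])
        geno = read_genotypes(tmp_path / "genotypes.csv")
        np.testing.assert_allclose(
            cd.heterozygosity(geno), cd.heterozygosity(sc.genotypes)
        )
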