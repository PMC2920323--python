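import itertools

import numpy as np
import pytest
import scipy.sparse as sp

import cropdispersal as cd
from cropdispersal.landscape import build_adjacency, center_distances
from cropdispersal.raster import distance_to_coast


def brute_force_neighbor_pairs(n_rows, n_cols, directions):
    """Enumeration oracle: undirected adjacent cell pairs on a full grid."""
    pairs = set()
    for (r1, c1), (r2, c2) in itertools.combinations(
        itertools.product(range(n_rows), range(n_cols)), 2
    ):
        dr, dc = abs(r1 - r2), abs(c1 - c2)
        if directions == 4 and dr + dc == 1:
            pairs.add(((r1, c1), (r2, c2)))
        elif directions == 8 and max(dr, dc) == 1:
            pairs.add(((r1, c1), (r2, c2)))
    return pairs


class TestAdjacency:
    @pytest.mark.parametrize(
        "shape, directions, expected_pairs",
        [
            ((3, 3), 8, 20),
            ((1, 2), 4, 1),
            ((2, 2), 4, 4),
            ((2, 2), 8, 6),
        ],
    )
    def test_connection_counts_match_enumeration(self, shape, directions, expected_pairs):
        assert (
            len(brute_force_neighbor_pairs(*shape, directions)) == expected_pairs
        )  # oracle agrees with the frozen count
        grid = cd.RasterGrid(np.ones(shape), 0.0, 0.0, 0.5)
        adj = build_adjacency(grid, directions)
        assert adj.nnz == 2 * expected_pairs
        assert (adj != adj.T).nnz == 0

    def test_structure_matches_enumeration_on_random_mask(self):
        rng = np.random.default_rng(11)
        values = (rng.random((5, 6)) < 0.7).astype(float)
        grid = cd.RasterGrid(values, 0.0, 0.0, 0.5)
        grid.values[grid.values == 0] = grid.nodata  # nodata cells are excluded
        adj = build_adjacency(grid, 8)
        expected = {
            (grid.rowcol_to_index(*a), grid.rowcol_to_index(*b))
            for a, b in brute_force_neighbor_pairs(5, 6, 8)
            if grid.valid_mask()[grid.rowcol_to_index(*a)]
            and grid.valid_mask()[grid.rowcol_to_index(*b)]
        }
        got = {(i, j) for i, j in zip(*adj.nonzero()) if i < j}
        assert got == expected

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            cd.RasterGrid(np.ones((0, 3)), 0.0, 0.0, 0.5)


class TestWaterConductance:
    def make(self, dbar, p1, p2):
        """Two-cell grid: one land, one water at distance-to-coast 2*dbar."""
        grid = cd.RasterGrid(np.array([[1.0, 0.0]]), 0.0, 0.0, 0.5)
        dtc = grid.like(np.array([[0.0, 2 * dbar]]))
        adj = build_adjacency(grid, 4)
        params = cd.LandscapeParams(p1=p1, p2=p2)
        return cd.water_conductance(adj, grid, dtc, params)

    def test_zero_coastal_distance_gives_p1(self):
        m = self.make(dbar=0.0, p1=0.37, p2=100.0)
        assert m[0, 1] == pytest.approx(0.37)

    def test_half_value_distance_halves_conductance(self):
        m = self.make(dbar=250.0, p1=0.8, p2=250.0)
        assert m[0, 1] == pytest.approx(0.4)

    def test_decay_formula_at_published_parameter_scale(self):
        # p1 = 0.23, p2 = 5310 km, dbar = 5310 km -> 0.115
        m = self.make(dbar=5310.0, p1=0.23, p2=5310.0)
        assert m[0, 1] == pytest.approx(0.115)

    def test_land_land_connections_absent(self, coastal_grid):
        adj = build_adjacency(coastal_grid, 8)
        dtc = distance_to_coast(coastal_grid)
        m = cd.water_conductance(adj, coastal_grid, dtc, cd.LandscapeParams(0.5, 500.0))
        land = coastal_grid.land_mask()
        i, j = m.nonzero()
        assert not np.any(land[i] & land[j])


class TestSymmetricNormalize:
    def test_single_connection_normalizes_to_one(self):
        m = sp.csr_matrix(np.array([[0.0, 3.7], [3.7, 0.0]]))
        out = cd.symmetric_normalize(m)
        assert out[0, 1] == pytest.approx(1.0)

    def test_eigenvalues_within_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.random((6, 6)) * (rng.random((6, 6)) < 0.5)
            m = sp.csr_matrix(np.triu(a, 1) + np.triu(a, 1).T)
            out = cd.symmetric_normalize(m).toarray()
            eig = np.linalg.eigvalsh(out)  # dense eigendecomposition oracle
            assert np.all(eig >= -1 - 1e-10) and np.all(eig <= 1 + 1e-10)

    def test_zero_rows_pass_through_and_symmetry_preserved(self):
        m = sp.csr_matrix(
            np.array([[0.0, 2.0, 0.0], [2.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        )
        out = cd.symmetric_normalize(m)
        assert out[2].nnz == 0
        assert (abs(out - out.T)).max() == 0


class TestDistanceCorrect:
    def test_equatorial_rook_connection_divided_by_arc_length(self):
        grid = cd.RasterGrid(np.ones((1, 2)), 0.0, -0.25, 0.5)
        m = build_adjacency(grid, 4)
        out = cd.distance_correct(m, grid)
        arc = cd.great_circle_km(0.25, 0.0, 0.75, 0.0)  # geodesic oracle
        assert arc == pytest.approx(55.6, abs=0.1)
        assert out[0, 1] == pytest.approx(1.0 / arc)

    def test_diagonal_weaker_than_rook_at_equal_conductance(self):
        grid = cd.RasterGrid(np.ones((2, 2)), 0.0, -0.5, 0.5)
        out = cd.distance_correct(build_adjacency(grid, 8), grid)
        rook = out[0, 1]
        diag = out[0, 3]
        assert diag < rook

    def test_west_east_connection_doubles_at_sixty_degrees(self):
        eq = cd.RasterGrid(np.ones((1, 2)), 0.0, -0.25, 0.5)
        high = cd.RasterGrid(np.ones((1, 2)), 0.0, 59.75, 0.5)
        c_eq = cd.distance_correct(build_adjacency(eq, 4), eq)[0, 1]
        c_high = cd.distance_correct(build_adjacency(high, 4), high)[0, 1]
        assert c_high / c_eq == pytest.approx(2.0, rel=0.01)  # cos(60deg) scaling


class TestAssembleLandscape:
    def test_all_land_connections_are_reciprocal_center_distances(self, all_land_grid):
        m = cd.assemble_landscape(all_land_grid, cd.LandscapeParams(0.5, 1000.0))
        coo = m.tocoo()
        d = center_distances(all_land_grid, m)
        np.testing.assert_allclose(coo.data, 1.0 / d)

    def test_symmetric_and_nonnegative(self, coastal_grid):
        m = cd.assemble_landscape(coastal_grid, cd.LandscapeParams(0.7, 300.0))
        assert (abs(m - m.T)).max() < 1e-15
        assert m.data.min() > 0

    def test_topology_invariant_to_parameters(self, coastal_grid):
        m1 = cd.assemble_landscape(coastal_grid, cd.LandscapeParams(0.1, 100.0))
        m2 = cd.assemble_landscape(coastal_grid, cd.LandscapeParams(5.0, 5000.0))
        assert m1.nnz == m2.nnz
        assert np.array_equal(m1.indices, m2.indices)

    def test_increasing_p1_never_decreases_water_conductance(self, coastal_grid):
        adj = build_adjacency(coastal_grid, 8)
        dtc = distance_to_coast(coastal_grid)
        lo = cd.water_conductance(adj, coastal_grid, dtc, cd.LandscapeParams(0.2, 400.0))
        hi = cd.water_conductance(adj, coastal_grid, dtc, cd.LandscapeParams(0.9, 400.0))
        assert np.all(hi.data >= lo.data)

    def test_p1_zero_disconnects_islands(self):
        # land strip, water gap, island
        values = np.array([[1.0, 1.0, 0.0, 1.0]])
        grid = cd.RasterGrid(values, 0.0, 0.0, 0.5)
        m = cd.assemble_landscape(grid, cd.LandscapeParams(0.0, 100.0))
        d = cd.least_cost_distance(m, 0)
        assert np.isinf(d[3])
        with_water = cd.assemble_landscape(grid, cd.LandscapeParams(0.5, 100.0))
        assert np.isfinite(cd.least_cost_distance(with_water, 0)[3])

    def test_all_water_with_zero_p1_raises(self):
        grid = cd.RasterGrid(np.zeros((3, 3)), 0.0, 0.0, 0.5)
        with pytest.raises(ValueError):
            cd.assemble_landscape(grid, cd.LandscapeParams(0.0, 100.0))

    def test_high_water_weight_makes_routes_hug_coast(self):
        # land column 0; water everywhere else. With p1 large and p2 small,
        # the cheapest route between two coastal water cells runs along the
        # coast (low distance-to-coast) rather than across open water.
        values = np.zeros((7, 7))
        values[:, 0] = 1.0
        grid = cd.RasterGrid(values, 0.0, 0.0, 0.5)
        m = cd.assemble_landscape(grid, cd.LandscapeParams(50.0, 30.0))
        start = grid.rowcol_to_index(0, 1)
        end = grid.rowcol_to_index(6, 1)
        from scipy.sparse.csgraph import dijkstra

        from cropdispersal.distances import cost_matrix

        _, pred = dijkstra(
            cost_matrix(m), directed=False, indices=start, return_predecessors=True
        )
        node, route_cols = end, []
        while node != start and node >= 0:
            route_cols.append(grid.index_to_rowcol(node)[1])
            node = pred[node]
        assert max(route_cols) <= 2  # stays in the coastal columns


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        {"p1": -0.1, "p2": 100.0},
        {"p1": 0.5, "p2": 0.0},
        {"p1": 0.5, "p2": 100.0, "directions": 6},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cd.LandscapeParams(**kwargs)
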