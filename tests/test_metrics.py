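import numpy as np
import pytest

import extdebt as ed
from extdebt.grid import DistanceMatrix
from extdebt.metrics import (concentration, connectivity_ifm, epoch_mean,
                             forest_area, proximity)


def _grid(res=10.0, extent=(-30, 30, 0, 60)):
    return ed.build_grid(extent, res)


def _two_cell_world():
    """Two adjacent equatorial cells with a hand-built distance matrix."""
    grid = ed.build_grid((-0.5, 0.5, 0, 2), 1.0)  # 1 x 2... need 2 cells
    return grid


def brute_force_ifm(areas, d, alpha):
    n = len(areas)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                out[i] += np.exp(-alpha * d[i, j]) * areas[j]
    return out


def brute_force_prox(areas, d, h):
    n = len(areas)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                if h is None or d[i, j] <= h:
                    out[i] += areas[j] / d[i, j] ** 2
    return out


class TestEpochMean:
    def test_constant_layers_mean_is_any_layer(self):
        grid = _grid()
        layers = [grid.layer(np.full(grid.n_cells, 0.3)) for _ in range(5)]
        assert np.allclose(epoch_mean(layers).values, 0.3)

    def test_linear_ramp_mean_is_midpoint(self):
        grid = _grid()
        annual = {y: grid.layer(np.full(grid.n_cells, y / 100)) for y in range(0, 101)}
        mean = epoch_mean(annual, window=(0, 100))
        assert np.allclose(mean.values, 0.5)

    def test_single_year_window_is_identity(self):
        grid = _grid()
        layer = grid.layer(np.random.default_rng(0).random(grid.n_cells))
        assert np.allclose(epoch_mean({2000: layer}, window=(2000, 2000)).values,
                           layer.values)

    def test_empty_window_rejected(self):
        grid = _grid()
        with pytest.raises(ValueError, match="empty"):
            epoch_mean({2000: grid.layer(np.ones(grid.n_cells))}, window=(1500, 1550))

    def test_grid_mismatch_rejected(self):
        a = _grid().layer(np.ones(_grid().n_cells))
        other = _grid(extent=(-30, 30, 0, 120))
        b = other.layer(np.ones(other.n_cells))
        with pytest.raises(ValueError, match="same grid"):
            epoch_mean([a, b])


class TestForestArea:
    def test_zero_and_full_fraction(self):
        grid = _grid()
        zero = forest_area(grid.layer(np.zeros(grid.n_cells)))
        full = forest_area(grid.layer(np.ones(grid.n_cells)))
        assert np.all(zero.land_values == 0)
        assert np.allclose(full.land_values, grid.cell_areas[grid.land_ids])

    def test_half_fraction_equatorial_cell(self):
        grid = ed.build_grid((-0.5, 0.5, 0, 1), 1.0)
        layer = forest_area(grid.layer(np.array([0.5])))
        assert layer.values[0] == pytest.approx(6182.094467804361, rel=1e-12)

    def test_fraction_out_of_bounds_rejected(self):
        grid = _grid()
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            forest_area(grid.layer(np.full(grid.n_cells, 1.5)))


class TestConnectivity:
    def test_two_cell_definition(self):
        grid = ed.build_grid((-0.5, 0.5, 0, 2), 1.0)
        dm = ed.distance_matrix(grid)
        d = dm.distances[0, 1]
        areas = grid.layer(np.array([100.0, 40.0]))
        ifm = connectivity_ifm(areas, dm, alpha=0.01)
        assert ifm.values[0] == pytest.approx(40.0 * np.exp(-0.01 * d), rel=1e-12)
        assert ifm.values[1] == pytest.approx(100.0 * np.exp(-0.01 * d), rel=1e-12)

    def test_infinite_decay_kills_connectivity(self):
        grid = _grid()
        dm = ed.distance_matrix(grid)
        areas = grid.layer(np.ones(grid.n_cells))
        ifm = connectivity_ifm(areas, dm, alpha=1e6)
        assert np.all(ifm.land_values < 1e-10)

    def test_linearity_in_areas(self):
        grid = _grid()
        dm = ed.distance_matrix(grid)
        a = grid.layer(np.random.default_rng(1).random(grid.n_cells))
        one = connectivity_ifm(a, dm, 0.001).land_values
        two = connectivity_ifm(a * 2.0, dm, 0.001).land_values
        assert np.allclose(two, 2 * one, rtol=1e-12)

    def test_nonpositive_alpha_rejected(self):
        grid = _grid()
        dm = ed.distance_matrix(grid)
        with pytest.raises(ValueError):
            connectivity_ifm(grid.layer(np.ones(grid.n_cells)), dm, alpha=0.0)

    def test_matches_brute_force(self):
        grid = _grid(res=5.0, extent=(-25, 25, 0, 50))
        dm = ed.distance_matrix(grid)
        vals = np.random.default_rng(2).random(grid.n_cells) * 1e4
        ifm = connectivity_ifm(grid.layer(vals), dm, alpha=0.002)
        expected = brute_force_ifm(vals, dm.distances, 0.002)
        assert np.allclose(ifm.land_values, expected[grid.land_ids], rtol=1e-12)

    def test_cutoff_removes_far_pairs(self):
        grid = _grid()
        dm = ed.distance_matrix(grid)
        vals = np.ones(grid.n_cells)
        near = connectivity_ifm(grid.layer(vals), dm, 0.001, cutoff=1500.0)
        all_pairs = connectivity_ifm(grid.layer(vals), dm, 0.001)
        assert np.all(near.land_values <= all_pairs.land_values)
        d = np.where(dm.distances > 1500.0, np.nan, dm.distances)
        expected = brute_force_ifm(vals, d, 0.001)
        assert np.allclose(near.land_values, expected, rtol=1e-12)


class TestProximity:
    def test_two_cell_definition(self):
        grid = ed.build_grid((-0.5, 0.5, 0, 2), 1.0)
        dm = ed.distance_matrix(grid)
        d = dm.distances[0, 1]
        prox = proximity(grid.layer(np.array([100.0, 40.0])), dm)
        assert prox.values[0] == pytest.approx(40.0 / d**2, rel=1e-12)

    def test_radius_below_min_distance_zeroes_everything(self):
        grid = _grid()
        dm = ed.distance_matrix(grid)
        prox = proximity(grid.layer(np.ones(grid.n_cells)), dm, h=1.0)
        assert np.all(prox.land_values == 0)

    def test_inverse_square_homogeneity(self):
        grid = _grid()
        dm = ed.distance_matrix(grid)
        doubled = DistanceMatrix(grid, dm.distances * 2.0)
        a = grid.layer(np.random.default_rng(3).random(grid.n_cells))
        p1 = proximity(a, dm).land_values
        p2 = proximity(a, doubled).land_values
        assert np.allclose(p2, p1 / 4.0, rtol=1e-12)

    def test_matches_brute_force(self):
        grid = _grid(res=5.0, extent=(-25, 25, 0, 50))
        dm = ed.distance_matrix(grid)
        vals = np.random.default_rng(4).random(grid.n_cells) * 1e4
        prox = proximity(grid.layer(vals), dm, h=2000.0)
        expected = brute_force_prox(vals, dm.distances, 2000.0)
        assert np.allclose(prox.land_values, expected[grid.land_ids], rtol=1e-12)


class TestConcentration:
    def test_uniform_interior_is_five_a(self):
        grid = _grid()
        conc = concentration(grid.layer(np.full(grid.n_cells, 7.0)))
        interior = 2 * grid.ncols + 3
        assert conc.values[interior] == pytest.approx(35.0)

    def test_polar_row_uniform_is_four_a(self):
        grid = ed.build_grid((-90, 90, -180, 180), 30.0)
        conc = concentration(grid.layer(np.full(grid.n_cells, 7.0)))
        assert conc.values[0] == pytest.approx(28.0)  # 3 neighbors + self

    def test_single_source_spreads_to_neighbors(self):
        grid = _grid()
        vals = np.zeros(grid.n_cells)
        focal = 2 * grid.ncols + 3
        vals[focal] = 11.0
        conc = concentration(grid.layer(vals))
        assert conc.values[focal] == 11.0
        nbrs = grid.neighbors(focal)
        assert np.allclose(conc.values[nbrs], 11.0)
        others = np.setdiff1d(np.arange(grid.n_cells), np.append(nbrs, focal))
        assert np.all(conc.values[others] == 0)

    def test_masked_neighbors_contribute_zero(self):
        mask = np.ones((6, 6), dtype=bool)
        mask[2, 3] = False
        grid = ed.build_grid((-30, 30, 0, 60), 10.0, land_mask=mask)
        conc = concentration(grid.layer(np.full(grid.n_cells, 1.0)))
        focal = 3 * grid.ncols + 3  # south of the masked cell
        assert conc.values[focal] == pytest.approx(4.0)

    def test_concentration_dominates_area(self, small_world):
        grid = small_world.grid
        areas = forest_area(small_world.fraction_2000s, grid)
        conc = concentration(areas, grid)
        ids = grid.land_ids
        assert np.all(conc.values[ids] >= areas.values[ids] - 1e-9)
        # Conc − A equals the sum of neighboring areas exactly
        focal = ids[len(ids) // 2]
        nbrs = grid.neighbors(focal)
        a = np.where(np.isfinite(areas.values), areas.values, 0.0)
        assert conc.values[focal] - a[focal] == pytest.approx(a[nbrs].sum(), rel=1e-12)


class TestMetricSet:
    def test_table_has_eight_predictors(self, small_world):
        dm = ed.distance_matrix(small_world.grid)
        mset = ed.compute_metric_set(small_world.fraction_1500s,
                                     small_world.fraction_2000s, dm)
        tab = mset.table()
        assert set(ed.PREDICTOR_NAMES) <= set(tab.columns)
        assert len(tab) == small_world.grid.n_land
        assert (tab[list(ed.PREDICTOR_NAMES)].to_numpy() >= 0).all()
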