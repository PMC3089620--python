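"""Friction grids, least-cost distances, Mantel tests and IBD slopes."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from phylogeokit.gendist import DistanceMatrix
from phylogeokit.landscape import (
    DemGrid,
    FrictionModel,
    effective_distance_matrix,
    friction_cost,
    friction_grid,
    ibd_partition,
    least_cost_distance,
    mantel,
    project_coordinates,
    read_ascii_grid,
    write_ascii_grid,
)

_SQRT2 = math.sqrt(2.0)


def brute_force_least_cost(cost, origin, dest, cellsize=1.0):
    """Exhaustive DFS over simple paths with branch-and-bound pruning."""
    nrows, ncols = cost.shape
    passable = np.isfinite(cost)
    best = [math.inf]

    def edges(r, c):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < nrows and 0 <= c2 < ncols):
                    continue
                if not passable[r2, c2]:
                    continue
                diag = dr != 0 and dc != 0
                if diag and not (passable[r, c2] or passable[r2, c]):
                    continue
                step = _SQRT2 if diag else 1.0
                yield r2, c2, 0.5 * (cost[r, c] + cost[r2, c2]) * step * cellsize

    seen = set()

    def dfs(r, c, acc):
        if acc >= best[0]:
            return
        if (r, c) == dest:
            best[0] = acc
            return
        seen.add((r, c))
        for r2, c2, w in edges(r, c):
            if (r2, c2) not in seen:
                dfs(r2, c2, acc + w)
        seen.discard((r, c))

    dfs(*origin, 0.0)
    return best[0]


class TestAsciiGrid:
    def test_round_trip(self, tmp_path):
        elev = np.array([[100.0, 200.0], [np.nan, 50.0]])
        dem = DemGrid(elev, xll=1000.0, yll=2000.0, cellsize=500.0)
        write_ascii_grid(dem, tmp_path / "g.asc")
        back = read_ascii_grid(tmp_path / "g.asc")
        assert (back.nrows, back.ncols, back.cellsize) == (2, 2, 500.0)
        assert back.xll == 1000.0 and back.yll == 2000.0
        assert np.isnan(back.elev[1, 0])
        np.testing.assert_allclose(back.elev[0], elev[0])

    def test_header_validation(self, tmp_path):
        (tmp_path / "bad.asc").write_text("ncols 2\nnrows 2\n1 2\n3 4\n")
        with pytest.raises(ValueError, match="header"):
            read_ascii_grid(tmp_path / "bad.asc")

    def test_cell_mapping_round_trip(self):
        dem = DemGrid(np.zeros((4, 6)), xll=0.0, yll=0.0, cellsize=10.0)
        for row, col in [(0, 0), (3, 5), (1, 4)]:
            x, y = dem.cell_center(row, col)
            assert dem.cell_of(x, y) == (row, col)

    def test_outside_extent_raises(self):
        dem = DemGrid(np.zeros((2, 2)), xll=0.0, yll=0.0, cellsize=10.0)
        with pytest.raises(ValueError, match="outside"):
            dem.cell_of(25.0, 5.0)


class TestFriction:
    def test_floor_at_sea_level(self):
        assert friction_cost(0.0) == 1.0
        assert friction_cost(-5.0) == 1.0

    def test_cap_impassable(self):
        assert friction_cost(2301.0) == math.inf
        assert friction_cost(2300.0) < math.inf

    def test_exponential_value(self):
        # 1.4142 e^(0.0035 * 1000)
        assert friction_cost(1000.0) == pytest.approx(1.4142 * math.exp(3.5), rel=1e-12)
        assert friction_cost(1000.0) == pytest.approx(46.83, abs=0.01)

    def test_nodata_impassable(self):
        assert friction_cost(float("nan")) == math.inf

    def test_grid_matches_scalar(self):
        dem = DemGrid(
            np.array([[0.0, 1000.0], [2400.0, np.nan]]), 0.0, 0.0, 10.0
        )
        grid = friction_grid(dem)
        assert grid[0, 0] == 1.0
        assert grid[0, 1] == pytest.approx(friction_cost(1000.0))
        assert math.isinf(grid[1, 0]) and math.isinf(grid[1, 1])

    def test_calibrated_mode_hits_cap_cost(self):
        model = FrictionModel.calibrated(cap_cost=5096.0)
        assert friction_cost(2300.0, model) == pytest.approx(5096.0, rel=1e-9)

    def test_linear_mode_monotone(self):
        model = FrictionModel(mode="linear")
        costs = [friction_cost(e, model) for e in (10, 500, 1500, 2300)]
        assert costs == sorted(costs)
        assert friction_cost(2301.0, model) == math.inf


class TestLeastCost:
    def test_origin_equals_dest(self):
        assert least_cost_distance(np.ones((3, 3)), (1, 1), (1, 1)) == 0.0

    def test_flat_rook_path(self):
        # 3 cells in a row, cost 1, cellsize 1: two edges of cost 1
        assert least_cost_distance(np.ones((1, 3)), (0, 0), (0, 2)) == pytest.approx(2.0)

    def test_wall_with_gap_matches_brute_force(self):
        cost = np.ones((5, 5))
        cost[2, :4] = np.inf
        d = least_cost_distance(cost, (0, 0), (4, 0))
        assert d == pytest.approx(brute_force_least_cost(cost, (0, 0), (4, 0)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_grids_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        cost = rng.uniform(0.5, 4.0, size=(5, 5))
        cost[rng.random((5, 5)) < 0.2] = np.inf
        cost[0, 0] = cost[4, 4] = 1.0
        d = least_cost_distance(cost, (0, 0), (4, 4))
        b = brute_force_least_cost(cost, (0, 0), (4, 4))
        assert d == pytest.approx(b) or (math.isinf(d) and math.isinf(b))

    def test_unreachable_is_inf(self):
        cost = np.ones((3, 3))
        cost[:, 1] = np.inf
        assert math.isinf(least_cost_distance(cost, (0, 0), (0, 2)))

    def test_impassable_endpoint_raises(self):
        cost = np.ones((2, 2))
        cost[0, 0] = np.inf
        with pytest.raises(ValueError, match="impassable"):
            least_cost_distance(cost, (0, 0), (1, 1))

    def test_no_corner_cutting_through_wall(self):
        # diagonal squeeze between two impassable cells is not allowed
        cost = np.ones((2, 2))
        cost[0, 1] = cost[1, 0] = np.inf
        assert math.isinf(least_cost_distance(cost, (0, 0), (1, 1)))

    def test_monotone_in_cell_cost(self):
        rng = np.random.default_rng(3)
        cost = rng.uniform(1.0, 2.0, size=(4, 4))
        d0 = least_cost_distance(cost, (0, 0), (3, 3))
        bumped = cost.copy()
        bumped[1, 1] += 5.0
        assert least_cost_distance(bumped, (0, 0), (3, 3)) >= d0 - 1e-12

    def test_triangle_inequality(self):
        rng = np.random.default_rng(4)
        cost = rng.uniform(0.5, 3.0, size=(5, 5))
        a, b, c = (0, 0), (2, 3), (4, 4)
        dab = least_cost_distance(cost, a, b)
        dbc = least_cost_distance(cost, b, c)
        dac = least_cost_distance(cost, a, c)
        assert dac <= dab + dbc + 1e-9


class TestEffectiveDistances:
    def _sites(self):
        return pd.DataFrame(
            {
                "site": ["p", "q", "r"],
                "lat": [0.0, 0.0, 0.3],
                "lon": [0.0, 0.4, 0.0],
            }
        )

    def test_flat_grid_proportional_to_octile(self):
        dem = DemGrid(np.zeros((60, 60)), -300_000.0, -300_000.0, 10_000.0)
        eff = effective_distance_matrix(self._sites(), dem, reference_lat=0.0)
        # expected: cell offsets at cost 1, octile metric x cellsize
        cells = {}
        for _, row in self._sites().iterrows():
            x, y = project_coordinates(row["lat"], row["lon"], 0.0)
            cells[row["site"]] = dem.cell_of(float(x) * 1000, float(y) * 1000)
        for a, b in [("p", "q"), ("p", "r"), ("q", "r")]:
            dr = abs(cells[a][0] - cells[b][0])
            dc = abs(cells[a][1] - cells[b][1])
            octile = (max(dr, dc) - min(dr, dc)) + _SQRT2 * min(dr, dc)
            assert eff.get(a, b) == pytest.approx(octile * 10_000.0, rel=1e-9)

    def test_full_ridge_unreachable(self):
        elev = np.zeros((20, 20))
        elev[10, :] = 3000.0
        dem = DemGrid(elev, -100_000.0, -100_000.0, 10_000.0)
        sites = pd.DataFrame(
            {"site": ["n", "s"], "lat": [0.5, -0.5], "lon": [0.0, 0.0]}
        )
        eff = effective_distance_matrix(sites, dem, reference_lat=0.0)
        assert math.isinf(eff.get("n", "s"))

    def test_barrier_inflates_effective_distance(self, two_basin_dataset):
        ds = two_basin_dataset
        sites = (
            ds.sample_table.groupby("site")
            .agg(lat=("lat", "mean"), lon=("lon", "mean"))
            .reset_index()
        )
        # without barrier: straight-line effective distance
        flat = DemGrid(
            np.zeros_like(ds.dem.elev), ds.dem.xll, ds.dem.yll, ds.dem.cellsize
        )
        eff_flat = effective_distance_matrix(sites, flat, reference_lat=ds.ref_lat)
        eff_ridge = effective_distance_matrix(
            sites, ds.dem, reference_lat=ds.ref_lat, snap_radius=10
        )
        # ridge forces a detour (or severs the route entirely)
        assert eff_ridge.get("a1", "b1") > eff_flat.get("a1", "b1")

    def test_unmappable_site_reported(self):
        elev = np.full((5, 5), 3000.0)
        dem = DemGrid(elev, -30_000.0, -30_000.0, 10_000.0)
        sites = pd.DataFrame({"site": ["x", "y"], "lat": [0.0, 0.1], "lon": [0.0, 0.1]})
        with pytest.raises(ValueError, match="x"):
            effective_distance_matrix(sites, dem, reference_lat=0.0)


class TestMantel:
    def _pair(self, rng, n=8):
        def sym(m):
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            return m

        labels = [f"s{i}" for i in range(n)]
        a = sym(rng.random((n, n)))
        b = sym(rng.random((n, n)))
        return DistanceMatrix(labels, a), DistanceMatrix(labels, b)

    def test_self_correlation_is_one(self, rng):
        a, _ = self._pair(rng)
        res = mantel(a, a, nperm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_anticorrelation_minus_one(self, rng):
        a, _ = self._pair(rng)
        vals = a.values.max() - a.values  # shifted positive, reversed order
        np.fill_diagonal(vals, 0.0)
        res = mantel(a, DistanceMatrix(a.labels, vals), nperm=49, seed=0)
        assert res.r == pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        a, b = self._pair(rng)
        res1 = mantel(a, b, nperm=49, seed=7)
        scaled = DistanceMatrix(b.labels, b.values * 3.7)
        res2 = mantel(a, scaled, nperm=49, seed=7)
        assert res1.r == pytest.approx(res2.r, abs=1e-12)
        assert res1.p == res2.p

    def test_constant_matrix_rejected(self):
        labels = ["a", "b", "c"]
        const = np.ones((3, 3)) - np.eye(3)
        vary = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        with pytest.raises(ValueError, match="constant"):
            mantel(DistanceMatrix(labels, const), DistanceMatrix(labels, vary), nperm=9)


class TestIbdPartition:
    def test_proportional_within_and_flat_between(self):
        labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
        geo = np.zeros((6, 6))
        rng = np.random.default_rng(2)
        base = rng.uniform(10, 100, size=(6, 6))
        geo = (base + base.T) / 2
        np.fill_diagonal(geo, 0.0)
        gen = 0.01 * geo  # genetic = c * geographic everywhere within
        basin_of = {l: l[0] for l in labels}
        # between-basin pairs: constant genetic distance
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j and basin_of[a] != basin_of[b]:
                    gen[i, j] = 0.5
        res = ibd_partition(
            DistanceMatrix(labels, gen), DistanceMatrix(labels, geo), basin_of
        )
        assert res.within_slopes["a"] == pytest.approx(0.01, abs=1e-12)
        assert res.within_slopes["b"] == pytest.approx(0.01, abs=1e-12)
        assert res.between_slope == pytest.approx(0.0, abs=1e-12)

    def test_small_basin_slope_undefined(self):
        labels = ["a1", "a2", "b1"]
        vals = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        res = ibd_partition(
            DistanceMatrix(labels, vals),
            DistanceMatrix(labels, vals * 2),
            {"a1": "a", "a2": "a", "b1": "b"},
        )
        assert res.within_slopes["a"] is None

    def test_scatter_classifies_pairs(self):
        labels = ["a1", "a2", "b1"]
        vals = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        res = ibd_partition(
            DistanceMatrix(labels, vals),
            DistanceMatrix(labels, vals),
            {"a1": "a", "a2": "a", "b1": "b"},
        )
        counts = res.scatter["stratum"].value_counts()
        assert counts["within"] == 1 and counts["between"] == 2


def test_synthetic_ibd_scenario_signs(rng):
    """Distance-proportional divergence within basins, uniform deep divergence
    between them: positive within slopes, non-positive between slope."""
    sites = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
    n = len(sites)
    pos = {s: (i * 10.0 + rng.normal(0, 1), (0.0 if s[0] == "a" else 500.0)) for i, s in enumerate(sites)}
    geo = np.zeros((n, n))
    gen = np.zeros((n, n))
    for i, a in enumerate(sites):
        for j, b in enumerate(sites):
            if i == j:
                continue
            d = math.hypot(pos[a][0] - pos[b][0], pos[a][1] - pos[b][1])
            geo[i, j] = d
            if a[0] == b[0]:
                gen[i, j] = 1e-4 * d
            else:
                gen[i, j] = 0.08 + rng.normal(0, 1e-4)
    gen = (gen + gen.T) / 2
    geo = (geo + geo.T) / 2
    np.fill_diagonal(gen, 0.0)
    np.fill_diagonal(geo, 0.0)
    res = ibd_partition(
        DistanceMatrix(sites, gen),
        DistanceMatrix(sites, geo),
        {s: s[0] for s in sites},
    )
    assert res.within_slopes["a"] > 0
    assert res.within_slopes["b"] > 0
    # uniform deep divergence between basins: slope indistinguishable from 0,
    # far below the positive within-basin signal
    assert res.between_slope <= 1e-5 < res.within_slopes["a"]
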