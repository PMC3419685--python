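"""Cost surfaces, least-cost and resistance distances, current maps,
and the residential-cluster classifier."""

import networkx as nx
import numpy as np
import pytest

from landgen.rasters import LandscapeRaster
from landgen.resistance import (
    SQRT2,
    CostSurface,
    build_cost_surface,
    build_multiclass_surface,
    classify_residential,
    current_map,
    euclidean_matrix,
    least_cost_matrix,
    resistance_matrix,
)


def surface_from_costs(costs):
    costs = np.asarray(costs, dtype=float)
    raster = LandscapeRaster(
        data=np.where(np.isnan(costs), -9999, 1).astype(int),
        xllcorner=0.0,
        yllcorner=0.0,
        cellsize=20.0,
    )
    return CostSurface(raster=raster, costs=costs)


def nx_graph(surface):
    """Explicit edge enumeration for the shortest-path oracle."""
    costs = surface.costs
    nrows, ncols = costs.shape
    g = nx.Graph()
    for r in range(nrows):
        for c in range(ncols):
            if np.isnan(costs[r, c]):
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < nrows and 0 <= cc < ncols):
                        continue
                    if np.isnan(costs[rr, cc]):
                        continue
                    w = 20.0 * (costs[r, c] + costs[rr, cc]) / 2.0
                    if dr and dc:
                        w *= SQRT2
                    g.add_edge((r, c), (rr, cc), weight=w)
    return g


class TestCostSurface:
    def test_uniform_when_cost_one(self, uniform_raster):
        s = build_cost_surface(uniform_raster, "oil_palm", 1)
        assert (s.costs == 1.0).all()

    def test_absent_class_warns(self, uniform_raster):
        with pytest.warns(UserWarning, match="absent"):
            s = build_cost_surface(uniform_raster, "oil_palm", 50)
        assert (s.costs == 1.0).all()

    def test_sweep_costs_set_focal_cells(self, uniform_raster):
        r = uniform_raster
        r.data[3:5, :] = 2  # oil palm band
        for cost in (10, 50, 100, 1000, 5000, 10000):
            s = build_cost_surface(r, "oil_palm", cost)
            assert (s.costs[3:5, :] == cost).all()
            assert (s.costs[0, :] == 1.0).all()

    def test_positive_costs_enforced(self):
        with pytest.raises(ValueError, match="positive"):
            surface_from_costs([[1.0, -1.0]])


class TestLeastCost:
    def test_straight_line_collapse(self):
        s = surface_from_costs(np.ones((10, 10)))
        r = s.raster
        pts = [r.rowcol_to_xy(5, 2), r.rowcol_to_xy(5, 7)]
        assert least_cost_matrix(s, pts).values[0, 1] == pytest.approx(100.0)

    def test_diagonal_convention(self):
        s = surface_from_costs(np.ones((10, 10)))
        r = s.raster
        pts = [r.rowcol_to_xy(2, 2), r.rowcol_to_xy(5, 5)]
        assert least_cost_matrix(s, pts).values[0, 1] == pytest.approx(
            3 * SQRT2 * 20.0
        )

    def test_chamfer_metric_on_uniform_costs(self):
        s = surface_from_costs(np.ones((15, 15)))
        r = s.raster
        rng = np.random.default_rng(0)
        cells = rng.integers(0, 15, size=(8, 2))
        pts = [r.rowcol_to_xy(rr, cc) for rr, cc in cells]
        m = least_cost_matrix(s, pts).values
        for i in range(8):
            for j in range(8):
                d_r = abs(int(cells[i, 0]) - int(cells[j, 0]))
                d_c = abs(int(cells[i, 1]) - int(cells[j, 1]))
                expect = 20.0 * (max(d_r, d_c) + (SQRT2 - 1) * min(d_r, d_c))
                assert m[i, j] == pytest.approx(expect, abs=1e-9)

    def test_matches_networkx_oracle_on_random_surfaces(self):
        rng = np.random.default_rng(42)
        costs = rng.uniform(0.5, 30.0, size=(20, 20))
        s = surface_from_costs(costs)
        g = nx_graph(s)
        cells = rng.integers(0, 20, size=(10, 2))
        pts = [s.raster.rowcol_to_xy(rr, cc) for rr, cc in cells]
        m = least_cost_matrix(s, pts).values
        checked = 0
        for i in range(10):
            for j in range(i + 1, 10):
                expect = nx.dijkstra_path_length(
                    g, tuple(cells[i]), tuple(cells[j])
                )
                assert m[i, j] == pytest.approx(expect, abs=1e-9)
                checked += 1
        assert checked == 45

    def test_disconnected_pair_infinite(self):
        costs = np.ones((3, 5))
        costs[:, 2] = np.nan
        s = surface_from_costs(costs)
        pts = [s.raster.rowcol_to_xy(1, 0), s.raster.rowcol_to_xy(1, 4)]
        with pytest.warns(UserWarning, match="disconnected"):
            m = least_cost_matrix(s, pts)
        assert np.isinf(m.values[0, 1])


class TestEuclidean:
    def test_three_four_five(self):
        m = euclidean_matrix([[0, 0], [3, 4]])
        assert m.values[0, 1] == pytest.approx(5.0)

    def test_identical_points(self):
        assert euclidean_matrix([[1, 1], [1, 1]]).values[0, 1] == 0.0

    def test_isometry_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 2))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = pts @ rot.T + np.array([5.0, -3.0])
        assert np.allclose(
            euclidean_matrix(pts).values, euclidean_matrix(moved).values
        )


class TestResistance:
    def test_series_law_on_corridor(self):
        s = surface_from_costs(np.ones((1, 6)))
        pts = [s.raster.rowcol_to_xy(0, 0), s.raster.rowcol_to_xy(0, 5)]
        res = resistance_matrix(s, pts)
        assert res.matrix.values[0, 1] == pytest.approx(5 * 20.0, abs=1e-8)

    def test_parallel_law_halves_resistance(self):
        # two disjoint corridors sharing only the endpoint cells
        N = 8
        costs = np.full((3, N), np.nan)
        costs[0, 1 : N - 1] = 1.0
        costs[2, 1 : N - 1] = 1.0
        costs[1, 0] = costs[1, N - 1] = 1.0
        s2 = surface_from_costs(costs)
        single = costs.copy()
        single[2, :] = np.nan
        s1 = surface_from_costs(single)
        pts = [s2.raster.rowcol_to_xy(1, 0), s2.raster.rowcol_to_xy(1, N - 1)]
        r2 = resistance_matrix(s2, pts).matrix.values[0, 1]
        r1 = resistance_matrix(s1, pts).matrix.values[0, 1]
        assert r1 == pytest.approx(2 * 20 * SQRT2 + (N - 3) * 20, abs=1e-8)
        assert r2 == pytest.approx(r1 / 2.0, abs=1e-8)

    def test_raising_path_cost_raises_resistance(self):
        base = np.ones((1, 5))
        bumped = base.copy()
        bumped[0, 2] = 10.0
        pts_of = lambda s: [
            s.raster.rowcol_to_xy(0, 0),
            s.raster.rowcol_to_xy(0, 4),
        ]
        s_lo = surface_from_costs(base)
        s_hi = surface_from_costs(bumped)
        assert (
            resistance_matrix(s_hi, pts_of(s_hi)).matrix.values[0, 1]
            > resistance_matrix(s_lo, pts_of(s_lo)).matrix.values[0, 1]
        )

    def test_resistance_below_least_cost(self):
        # parallel routes can only reduce effective resistance
        rng = np.random.default_rng(9)
        for _ in range(10):
            costs = rng.uniform(0.5, 5.0, size=(8, 8))
            s = surface_from_costs(costs)
            pts = [s.raster.rowcol_to_xy(0, 0), s.raster.rowcol_to_xy(7, 7)]
            r = resistance_matrix(s, pts).matrix.values[0, 1]
            lc = least_cost_matrix(s, pts).values[0, 1]
            assert r <= lc + 1e-9


class TestCurrentMap:
    def test_conservation_and_symmetry(self):
        raster = LandscapeRaster(
            data=np.ones((9, 9), dtype=int), xllcorner=0, yllcorner=0, cellsize=20
        )
        s = build_cost_surface(raster, "forest", 1)
        # mirror-symmetric source placement across the vertical midline
        pts = np.array([raster.rowcol_to_xy(4, 1), raster.rowcol_to_xy(4, 7)])
        res = current_map(s, pts, np.array([1.0, 1.0]), buffer=1000.0)
        assert res.residual < res.tol
        cur = res.current
        assert np.allclose(cur, cur[:, ::-1], atol=1e-8)

    def test_matches_dense_solver_on_tiny_grid(self):
        raster = LandscapeRaster(
            data=np.ones((3, 3), dtype=int), xllcorner=0, yllcorner=0, cellsize=20
        )
        s = build_cost_surface(raster, "forest", 1)
        pts = np.array([raster.rowcol_to_xy(0, 0), raster.rowcol_to_xy(2, 2)])
        res = current_map(s, pts, np.array([1.0, 1.0]), buffer=1000.0)
        # dense oracle: build Laplacian explicitly, one focal at a time
        from landgen.resistance import _conductance_laplacian, _grid_edges

        lap, _ = _conductance_laplacian(s)
        dense = lap.toarray()
        u, v, w = _grid_edges(s)
        cond = 1.0 / w
        total = np.zeros(9)
        nodes = [0, 8]
        for focal, other in ((0, 1), (1, 0)):
            keep = [i for i in range(9) if i != nodes[focal]]
            b = np.zeros(9)
            b[nodes[other]] = 1.0
            volts = np.zeros(9)
            volts[keep] = np.linalg.solve(
                dense[np.ix_(keep, keep)], b[keep]
            )
            edge_cur = cond * (volts[u] - volts[v])
            node_cur = np.zeros(9)
            np.add.at(node_cur, u, np.abs(edge_cur))
            np.add.at(node_cur, v, np.abs(edge_cur))
            total += 0.5 * node_cur
        assert np.allclose(res.current.ravel(), total, atol=1e-8)

    def test_multiclass_surface_costs(self, uniform_raster):
        r = uniform_raster
        r.data[0, 0] = 2
        s = build_multiclass_surface(r)
        assert s.costs[0, 0] == 20.0 and s.costs[1, 1] == 1.0


class TestResidential:
    def test_blocks_80m_apart_merge_to_residential(self):
        mask = np.zeros((40, 40), bool)
        mask[10:15, 5:15] = True    # 50 cells = 2 ha
        mask[10:15, 19:29] = True   # 80 m gap
        out = classify_residential(mask, 20.0)
        assert set(np.unique(out[mask])) == {5}

    def test_blocks_120m_apart_stay_small(self):
        mask = np.zeros((40, 40), bool)
        mask[10:15, 5:15] = True
        mask[10:15, 21:31] = True   # 120 m gap
        out = classify_residential(mask, 20.0)
        assert set(np.unique(out[mask])) == {6}

    def test_exactly_three_hectares_is_not_residential(self):
        mask = np.zeros((40, 40), bool)
        mask[5:10, 5:20] = True     # 75 cells = 3.0 ha exactly
        out = classify_residential(mask, 20.0)
        assert set(np.unique(out[mask])) == {6}
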