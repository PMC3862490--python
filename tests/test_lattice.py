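import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate

import cartrend as ct
from cartrend.lattice import EARTH_RADIUS_KM, Cell


class TestAssignRoute:
    @pytest.mark.parametrize(
        "lon, lat, res, expected",
        [
            (-77.3, 39.6, 1, (-78, 39)),
            (-77.0, 39.0, 1, (-77, 39)),  # half-open boundary starts its own block
            (0.5, -0.5, 1, (0, -1)),
            (10.2, 45.7, 2, (10, 44)),
        ],
    )
    def test_floor_convention(self, lon, lat, res, expected):
        assert ct.assign_route(lon, lat, res) == expected

    @pytest.mark.parametrize(
        "lon, lat", [(np.nan, 0), (0, np.inf), (180.0, 0), (-181, 0), (0, 90), (0, -90)]
    )
    def test_rejects_bad_coordinates(self, lon, lat):
        with pytest.raises(ValueError):
            ct.assign_route(lon, lat, 1)

    @given(
        lon=st.floats(-180, 179.999), lat=st.floats(-89.9, 89.9),
        res=st.sampled_from([0.5, 1.0, 2.0]),
    )
    def test_point_lies_in_assigned_block(self, lon, lat, res):
        cid = ct.assign_route(lon, lat, res)
        assert Cell(cid, res).contains(lon, lat)


class TestCellArea:
    def test_equatorial_degree_cell(self):
        # closed form cross-checked below by 2-D numerical integration
        assert ct.cell_area((0, 1, 1, 0)) == pytest.approx(12364, abs=1)

    @pytest.mark.parametrize("lat", [-80, -45, 0, 30, 60, 89])
    def test_matches_numerical_integration(self, lat):
        area = ct.cell_area((10, lat + 1, 11, lat))
        num, err = integrate.dblquad(
            lambda phi, lam: EARTH_RADIUS_KM**2 * math.cos(phi),
            math.radians(10), math.radians(11),
            math.radians(lat), math.radians(lat + 1),
        )
        assert area == pytest.approx(num, rel=1e-8)

    def test_degenerate_and_inverted(self):
        assert ct.cell_area((5, 1, 5, 0)) == 0.0
        with pytest.raises(ValueError):
            ct.cell_area((5, 0, 4, 1))

    def test_symmetric_about_equator(self):
        assert ct.cell_area((0, 45, 1, 44)) == pytest.approx(
            ct.cell_area((0, -44, 1, -45)), rel=1e-14
        )

    def test_globe_sums_to_sphere_area(self):
        total = sum(
            ct.cell_area((lon, lat + 1, lon + 1, lat))
            for lon in range(-180, 180)
            for lat in range(-90, 90)
        )
        assert total == pytest.approx(4 * math.pi * EARTH_RADIUS_KM**2, rel=1e-10)

    @pytest.mark.parametrize("lat", [-60, 0, 37])
    def test_latitude_band_matches_analytic(self, lat):
        band = sum(ct.cell_area((lon, lat + 1, lon + 1, lat)) for lon in range(-180, 180))
        analytic = (
            2 * math.pi * EARTH_RADIUS_KM**2
            * (math.sin(math.radians(lat + 1)) - math.sin(math.radians(lat)))
        )
        assert band == pytest.approx(analytic, rel=1e-10)

    def test_area_decreases_with_latitude(self):
        areas = [ct.cell_area((0, la + 1, 1, la)) for la in range(0, 89)]
        assert all(a > b for a, b in zip(areas, areas[1:]))


class TestBuildLattice:
    def test_l_shape_rook_counts(self):
        lat = ct.build_lattice([(0, 0), (1, 0), (0, 1)], connectivity="strict")
        n = {c.id: k for c, k in zip(lat.cells, lat.n)}
        assert n == {(0, 0): 2, (1, 0): 1, (0, 1): 1}

    def test_3x3_rook_neighbor_counts(self, grid_3x3):
        # brute-force enumeration of shared edges
        ids = [c.id for c in grid_3x3.cells]
        expect = {
            cid: sum(
                1 for o in ids if abs(o[0] - cid[0]) + abs(o[1] - cid[1]) == 1
            )
            for cid in ids
        }
        got = {c.id: int(k) for c, k in zip(grid_3x3.cells, grid_3x3.n)}
        assert got == expect
        center = got[(1, 1)]
        assert center == 4
        assert sorted(got.values()) == [2, 2, 2, 2, 3, 3, 3, 3, 4]

    @pytest.mark.parametrize("n, m", [(2, 5), (4, 4), (1, 6)])
    def test_full_rectangle_closed_form(self, n, m):
        ids = [(i, j) for i in range(n) for j in range(m)]
        lat = ct.build_lattice(ids, connectivity="strict")
        counts = {c.id: int(k) for c, k in zip(lat.cells, lat.n)}
        for (i, j), k in counts.items():
            # corners 2, edges 3, interior 4 (degenerate 1-wide rows adapt)
            assert k == sum([i > 0, i < n - 1, j > 0, j < m - 1])

    def test_disconnected_strict_errors_naming_components(self):
        with pytest.raises(ValueError, match="components"):
            ct.build_lattice([(0, 0), (2, 0)], connectivity="strict")

    def test_largest_component_drops_and_warns(self):
        with pytest.warns(UserWarning, match="dropping"):
            lat = ct.build_lattice(
                [(0, 0), (1, 0), (2, 0), (5, 5)], connectivity="largest-component"
            )
        assert len(lat) == 3

    def test_bridge_connects_components(self):
        lat = ct.build_lattice(
            [(0, 0), (1, 0), (5, 0), (6, 0)], connectivity="bridge"
        )
        import networkx as nx

        assert nx.is_connected(lat.graph())
        assert len(lat) == 4

    def test_queen_scheme_adds_diagonals(self):
        lat = ct.build_lattice([(0, 0), (1, 1)], scheme="queen", connectivity="strict")
        assert lat.n.tolist() == [1, 1]

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError, match="empty"):
            ct.build_lattice([])

    def test_buffer_ring_grows_grid(self):
        lat = ct.build_lattice([(0, 0)], buffer=1)
        assert len(lat) == 5  # cell + 4 rook neighbors

    @given(
        st.sets(
            st.tuples(st.integers(0, 4), st.integers(0, 4)), min_size=2, max_size=12
        )
    )
    def test_adjacency_symmetric_zero_diagonal(self, ids):
        try:
            lat = ct.build_lattice(sorted(ids), connectivity="bridge")
        except ValueError:
            return  # single isolated cell
        W = lat.W.toarray()
        assert np.array_equal(W, W.T)
        assert not W.diagonal().any()
        assert np.array_equal(W.sum(axis=1), lat.n)
        assert np.allclose(lat.M * lat.n, 1.0)


class TestSurveyDataset:
    def _df(self, **over):
        base = dict(
            route_id=["r1", "r1", "r2"],
            observer_id=["a", "b", "a"],
            year=[2000, 2001, 2000],
            count=[3, 0, 5],
            start_lon=[0.5, 0.5, 1.5],
            start_lat=[0.5, 0.5, 0.5],
        )
        base.update(over)
        return pd.DataFrame(base)

    def test_basic_indexing(self):
        ds = ct.SurveyDataset(self._df())
        assert ds.n_records == 3
        assert ds.n_years == 2
        assert ds.cell_ids == [(0, 0), (0, 0), (1, 0)]
        assert ds.n_observers == 3  # observer-route pairs

    def test_observer_mode_collapses_pairs(self):
        ds = ct.SurveyDataset(self._df(), observer_mode="observer")
        assert ds.n_observers == 2

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="negative"):
            ct.SurveyDataset(self._df(count=[3, -1, 5]))

    def test_rejects_duplicates(self):
        df = self._df(observer_id=["a", "a", "a"], year=[2000, 2000, 2000])
        with pytest.raises(ValueError, match="duplicated"):
            ct.SurveyDataset(df)

    def test_every_route_in_exactly_one_cell(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "route_id": [f"r{i}" for i in range(50)],
                "observer_id": "x",
                "year": 2000,
                "count": 1,
                "start_lon": rng.uniform(-10, 10, 50),
                "start_lat": rng.uniform(30, 40, 50),
            }
        )
        df = pd.concat([df, df.assign(year=2001)])
        ds = ct.SurveyDataset(df)
        for cid, (lon, latd) in zip(
            ds.cell_ids, df[["start_lon", "start_lat"]].itertuples(index=False)
        ):
            assert Cell(cid).contains(lon, latd)
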