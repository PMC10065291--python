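import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from heatlag import exposure
from heatlag.exposure import IdwParams, NoNeighborError


class TestIdwPredict:
    def test_single_neighbor_returns_nearest(self):
        stations = np.array([[0.0, 0.0], [10.0, 0.0]])
        v = exposure.idw_predict([1.0, 0.0], stations, [5.0, 50.0],
                                 IdwParams(2.0, 1))
        assert v == 5.0

    def test_hand_computed_two_station_case(self):
        # distances 1 and 2 km, values 20 and 30, p=1:
        # (20/1 + 30/2) / (1 + 1/2) = 23.333...
        stations = np.array([[1.0, 0.0], [2.0, 0.0]])
        v = exposure.idw_predict([0.0, 0.0], stations, [20.0, 30.0],
                                 IdwParams(1.0, 2))
        assert v == pytest.approx(70 / 3, abs=1e-12)

    @pytest.mark.parametrize("p,k", [(1.0, 1), (2.0, 2), (3.0, 3)])
    def test_shared_value_is_returned_for_any_params(self, p, k):
        stations = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
        v = exposure.idw_predict([0.5, 0.5], stations, [7.0, 7.0, 7.0],
                                 IdwParams(p, k))
        assert v == pytest.approx(7.0)

    def test_coincident_station_short_circuit(self):
        stations = np.array([[0.0, 0.0], [1.0, 0.0]])
        v = exposure.idw_predict([0.0, 0.0], stations, [3.0, 99.0],
                                 IdwParams(2.0, 2))
        assert v == 3.0

    def test_no_neighbor_in_radius(self):
        stations = np.array([[10.0, 0.0]])
        with pytest.raises(NoNeighborError, match="no station within"):
            exposure.idw_predict([0.0, 0.0], stations, [1.0],
                                 IdwParams(2.0, 1, search_radius_km=5.0))

    def test_station_order_invariance_and_far_station(self):
        stations = np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 3.0]])
        vals = np.array([10.0, 20.0, 30.0])
        params = IdwParams(2.0, 3)
        a = exposure.idw_predict([0.2, 0.1], stations, vals, params)
        perm = [2, 0, 1]
        b = exposure.idw_predict([0.2, 0.1], stations[perm], vals[perm], params)
        assert a == pytest.approx(b, abs=1e-12)
        # a station beyond the search radius changes nothing
        bounded = IdwParams(2.0, 3, search_radius_km=5.0)
        base = exposure.idw_predict([0.2, 0.1], stations, vals, bounded)
        plus = exposure.idw_predict(
            [0.2, 0.1],
            np.vstack([stations, [100.0, 100.0]]),
            np.append(vals, 999.0),
            bounded,
        )
        assert base == pytest.approx(plus, abs=1e-12)

    @given(
        vals=st.lists(st.floats(-30, 50), min_size=3, max_size=6),
        p=st.sampled_from([1.0, 1.5, 2.0, 2.5, 3.0]),
        x=st.floats(0, 10),
        y=st.floats(0, 10),
    )
    def test_convex_combination_bounds(self, vals, p, x, y):
        n = len(vals)
        rng = np.random.default_rng(42)
        stations = rng.uniform(0, 10, (n, 2))
        v = exposure.idw_predict([x, y], stations, vals, IdwParams(p, n))
        assert min(vals) - 1e-9 <= v <= max(vals) + 1e-9


class TestLoocv:
    def test_constant_field_tie_break(self):
        stations = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0], [5.0, 5.0]])
        vals = np.full((4, 10), 23.0)
        best, scores = exposure.loocv_select(stations, vals)
        assert (best.power, best.n_neighbors) == (1.0, 1)
        assert np.allclose(scores["rmse"], 0.0)

    def test_rmse_at_least_mae_everywhere(self, rng):
        stations = rng.uniform(0, 30, (6, 2))
        vals = 25 + rng.normal(0, 2, (6, 40))
        _, scores = exposure.loocv_select(stations, vals)
        ok = np.isfinite(scores["rmse"])
        assert np.all(scores.loc[ok, "rmse"] >= scores.loc[ok, "mae"] - 1e-12)

    @pytest.mark.parametrize("gen_p", [1.0, 2.0, 3.0])
    def test_recovers_generating_parameters(self, gen_p):
        # field exactly self-consistent under leave-one-out IDW at
        # (gen_p, k=3) plus tiny noise: LOOCV must select that combination
        from heatlag.synthetic import generate_idw_selfconsistent_field

        pts, vals = generate_idw_selfconsistent_field(seed=1, power=gen_p)
        best, _ = exposure.loocv_select(pts, vals)
        assert (best.power, best.n_neighbors) == (gen_p, 3)

    def test_matches_brute_force_loocv(self, rng):
        # oracle equivalence: straightforward per-station re-implementation
        stations = rng.uniform(0, 20, (5, 2))
        vals = 24 + rng.normal(0, 2, (5, 15))
        _, scores = exposure.loocv_select(
            stations, vals, powers=(1.0, 2.0), n_neighbors=(1, 2)
        )
        for _, row in scores.iterrows():
            params = IdwParams(row["power"], int(row["n_neighbors"]))
            errs = []
            for i in range(5):
                others = [j for j in range(5) if j != i]
                for d in range(15):
                    pred = exposure.idw_predict(
                        stations[i], stations[others], vals[others, d], params
                    )
                    errs.append(pred - vals[i, d])
            errs = np.asarray(errs)
            assert row["rmse"] == pytest.approx(np.sqrt(np.mean(errs**2)))
            assert row["mae"] == pytest.approx(np.mean(np.abs(errs)))


class TestGridAndBuffer:
    def test_constant_station_values_give_constant_grid(self):
        stations = np.array([[0.0, 0.0], [4.0, 4.0]])
        centers, field = exposure.grid_interpolate(
            stations, np.array([5.0, 5.0]), IdwParams(2.0, 2)
        )
        assert np.allclose(field, 5.0)

    def test_cell_containing_station_returns_station_value(self):
        stations = np.array([[0.5, 0.5], [3.5, 3.5]])
        centers, field = exposure.grid_interpolate(
            stations, np.array([11.0, 22.0]), IdwParams(2.0, 2),
            bbox=(0, 0, 4, 4),
        )
        i = np.argmin(((centers - [0.5, 0.5]) ** 2).sum(axis=1))
        assert field[i] == 11.0

    def test_field_bounded_by_station_range(self, rng):
        stations = rng.uniform(0, 10, (5, 2))
        vals = rng.uniform(18, 32, 5)
        _, field = exposure.grid_interpolate(stations, vals, IdwParams(2.0, 5))
        assert field.min() >= vals.min() - 1e-9
        assert field.max() <= vals.max() + 1e-9

    def test_buffer_mean_of_four_cells(self):
        centers = np.array([[0.5, 0.5], [-0.5, 0.5], [0.5, -0.5], [-0.5, -0.5]])
        v = exposure.buffer_average([0.0, 0.0], centers,
                                    np.array([1.0, 2.0, 3.0, 4.0]), 1.0)
        assert v == 2.5

    def test_constant_field_buffer(self):
        centers = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        v = exposure.buffer_average([0.3, 0.3], centers, np.full(3, 9.0), 1.0)
        assert v == 9.0

    def test_shrinking_radius_converges_to_containing_cell(self):
        centers = np.array([[0.5, 0.5], [1.5, 0.5], [0.5, 1.5], [1.5, 1.5]])
        field = np.array([10.0, 20.0, 30.0, 40.0])
        point = [0.6, 0.6]
        vals = [
            exposure.buffer_average(point, centers, field, r)
            for r in (2.0, 1.0, 0.5, 0.2)
        ]
        assert vals[-1] == 10.0
        assert abs(vals[-1] - 10.0) <= abs(vals[0] - 10.0)

    def test_empty_buffer_falls_back_to_point_idw(self):
        centers = np.array([[50.0, 50.0]])
        stations = np.array([[0.0, 0.0], [2.0, 0.0]])
        svals = np.array([20.0, 30.0])
        v = exposure.buffer_average(
            [1.0, 0.0], centers, np.array([99.0]), 1.0,
            stations=stations, station_values=svals,
            params=IdwParams(1.0, 2),
        )
        assert v == 25.0  # equidistant stations, p=1

    def test_empty_buffer_without_fallback_raises(self):
        with pytest.raises(NoNeighborError):
            exposure.buffer_average([0, 0], np.array([[9.0, 9.0]]),
                                    np.array([1.0]), 1.0)


class TestAbsoluteHumidity:
    def test_dry_air_is_zero(self):
        assert exposure.absolute_humidity(30.0, 0.0) == 0.0

    def test_saturated_tropical_day(self):
        # Magnus form at T=30, RH=100: es = 6.112*exp(17.62*30/273.12)
        # = 42.344 hPa -> AH = 216.7*42.344/303.15 = 30.26 g/m^3
        assert exposure.absolute_humidity(30.0, 100.0) == pytest.approx(
            30.26, abs=0.05
        )

    def test_monotone_in_temperature_and_humidity(self):
        assert exposure.absolute_humidity(25, 60) < exposure.absolute_humidity(30, 60)
        assert exposure.absolute_humidity(25, 60) < exposure.absolute_humidity(25, 70)

    @pytest.mark.parametrize("t,rh", [(-30, 50), (70, 50), (25, -1), (25, 101)])
    def test_domain_errors(self, t, rh):
        with pytest.raises(ValueError):
            exposure.absolute_humidity(t, rh)


def test_cv_score_invariant():
    with pytest.raises(ValueError, match="rmse"):
        exposure.CvScore(IdwParams(1.0, 1), rmse=0.5, mae=0.9)


def test_project_lonlat_city_scale():
    xy = exposure.project_lonlat(
        np.array([-43.2, -43.2, -43.1]), np.array([-22.9, -22.8, -22.9])
    )
    d_lat = np.sqrt(((xy[1] - xy[0]) ** 2).sum())
    assert d_lat == pytest.approx(11.1, abs=0.2)  # 0.1 deg latitude in km
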