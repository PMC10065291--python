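import numpy as np
import pandas as pd
import pytest

from heatlag import weather
from heatlag.weather import StationSeries


def _series(values, start="2014-01-01", sid="A", x=0.0, y=0.0):
    cal = pd.date_range(start, periods=len(values), freq="D")
    return StationSeries(sid, x, y, cal, np.asarray(values, dtype=float))


class TestAggregateHourly:
    def test_full_day_of_identical_readings(self):
        idx = pd.date_range("2015-01-01", periods=24, freq="h")
        out = weather.aggregate_hourly_to_daily(pd.Series(25.0, index=idx))
        assert out.iloc[0] == 25.0

    def test_mean_of_two_readings_with_permissive_minimum(self):
        idx = pd.to_datetime(["2015-01-01 01:00", "2015-01-01 13:00"])
        out = weather.aggregate_hourly_to_daily(
            pd.Series([20.0, 30.0], index=idx), min_hours=1
        )
        assert out.iloc[0] == 25.0

    def test_day_below_minimum_hours_is_missing(self):
        idx = pd.date_range("2015-01-01", periods=10, freq="h")
        out = weather.aggregate_hourly_to_daily(pd.Series(20.0, index=idx))
        assert np.isnan(out.iloc[0])

    def test_empty_input(self):
        out = weather.aggregate_hourly_to_daily(pd.Series(dtype=float))
        assert out.empty


class TestQcFilter:
    def test_complete_station_kept(self):
        kept, rep = weather.qc_filter([_series(np.ones(730))])
        assert len(kept) == 1
        assert rep.overall["kept"].all()

    def test_bad_year_drops_station(self):
        # 25% missing in the first year, ~10% overall -> dropped
        v = np.ones(730)
        v[: int(0.25 * 365)] = np.nan
        kept, rep = weather.qc_filter([_series(np.ones(730)), _series(v, sid="B")])
        assert [s.station_id for s in kept] == ["A"]

    def test_overall_rule_catches_uniform_18pct(self):
        v = np.ones(730)
        for start in (0, 365):  # 18% missing in each year
            v[start : start + 66] = np.nan
        kept, _ = weather.qc_filter([_series(np.ones(730)), _series(v, sid="B")])
        assert [s.station_id for s in kept] == ["A"]

    def test_all_dropped_is_hard_error(self):
        v = np.ones(365)
        v[:200] = np.nan
        with pytest.raises(ValueError, match="all stations dropped"):
            weather.qc_filter([_series(v)])


@pytest.fixture()
def correlated_pair(rng):
    t = np.arange(500.0)
    base = 24 + 4 * np.cos(2 * np.pi * (t - 15) / 365.25) + rng.normal(0, 1.5, 500)
    return base


class TestEmImpute:
    def test_identity_on_complete_data(self, correlated_pair):
        s1 = _series(correlated_pair)
        s2 = _series(correlated_pair + 3, sid="B", x=1.0)
        res = weather.em_impute([s1, s2])
        assert res.n_iter == 0
        assert np.array_equal(res.stations[0].values, s1.values)

    def test_correlated_stations_conditional_mean(self, correlated_pair):
        # s2 = s1 + 3 exactly: the conditional mean of a missing s2 day given
        # s1 is s1 + 3, so the imputation must land within 0.05 degC of it
        v2 = correlated_pair + 3.0
        v2[200] = np.nan
        res = weather.em_impute(
            [_series(correlated_pair), _series(v2, sid="B", x=1.0)]
        )
        assert res.converged
        got = res.stations[1].values[200]
        assert abs(got - (correlated_pair[200] + 3.0)) < 0.05

    def test_observed_entries_never_altered(self, correlated_pair, rng):
        v2 = correlated_pair + rng.normal(0, 0.5, 500)
        v2[rng.choice(500, 30, replace=False)] = np.nan
        s1, s2 = _series(correlated_pair), _series(v2, sid="B", x=1.0)
        res = weather.em_impute([s1, s2])
        obs = ~np.isnan(v2)
        assert np.array_equal(res.stations[1].values[obs], v2[obs])

    def test_monotone_observed_loglik(self, correlated_pair, rng):
        v1 = correlated_pair.copy()
        v2 = correlated_pair + rng.normal(0, 1.0, 500)
        v1[rng.choice(500, 40, replace=False)] = np.nan
        v2[rng.choice(500, 40, replace=False)] = np.nan
        res = weather.em_impute([_series(v1), _series(v2, sid="B", x=1.0)])
        assert np.all(np.diff(res.loglik_trace) >= -1e-6)

    def test_leading_block_bounded(self, correlated_pair):
        v2 = correlated_pair + 3.0
        v2[:30] = np.nan
        res = weather.em_impute(
            [_series(correlated_pair), _series(v2, sid="B", x=1.0)]
        )
        block = res.stations[1].values[:30]
        obs = v2[30:]
        sd = obs.std()
        assert np.all(np.isfinite(block))
        assert block.min() > obs.min() - 3 * sd
        assert block.max() < obs.max() + 3 * sd

    def test_station_order_invariance(self, correlated_pair, rng):
        v2 = correlated_pair + rng.normal(0, 0.8, 500)
        v2[rng.choice(500, 25, replace=False)] = np.nan
        s1, s2 = _series(correlated_pair), _series(v2, sid="B", x=1.0)
        a = weather.em_impute([s1, s2]).stations
        b = weather.em_impute([s2, s1]).stations
        assert np.allclose(a[1].values, b[0].values, atol=1e-8)

    def test_beats_seasonal_mean_infill(self, rng):
        # MCAR 5% missingness: EM imputation must not lose to the oracle
        # baseline of per-station seasonal-spline infill
        from heatlag.weather import _time_spline_design

        t = np.arange(730.0)
        season = 24 + 4 * np.cos(2 * np.pi * (t - 15) / 365.25)
        common = rng.normal(0, 1.5, 730)
        truth = [season + common + rng.normal(0, 0.4, 730) for _ in range(4)]
        gappy, masks = [], []
        for j, v in enumerate(truth):
            vv = v.copy()
            m = rng.random(730) < 0.05
            vv[m] = np.nan
            gappy.append(_series(vv, sid=f"S{j}", x=float(j)))
            masks.append(m)
        res = weather.em_impute(gappy)
        Z = _time_spline_design(730, 2.0, 5)
        err_em, err_base = [], []
        for j, (v, m) in enumerate(zip(truth, masks)):
            obs = ~m
            beta = np.linalg.lstsq(Z[obs], v[obs], rcond=None)[0]
            err_base.extend(((Z @ beta)[m] - v[m]) ** 2)
            err_em.extend((res.stations[j].values[m] - v[m]) ** 2)
        assert np.sqrt(np.mean(err_em)) <= np.sqrt(np.mean(err_base))

    def test_requires_two_stations(self, correlated_pair):
        with pytest.raises(ValueError, match=">= 2 stations"):
            weather.em_impute([_series(correlated_pair)])


def test_station_series_invariants():
    cal = pd.date_range("2014-01-01", periods=5, freq="D")
    with pytest.raises(ValueError, match="consecutive"):
        StationSeries("A", 0, 0, cal[[0, 1, 3, 4, 2]], np.ones(5))
    with pytest.raises(ValueError, match="equal length"):
        StationSeries("A", 0, 0, cal, np.ones(4))
    with pytest.raises(ValueError, match="finite"):
        StationSeries("A", 0, 0, cal, np.array([1, 2, np.inf, 4, 5.0]))
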