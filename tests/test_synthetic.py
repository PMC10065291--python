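import numpy as np
import pandas as pd
import pytest

import heatlag as hl
from heatlag import synthetic


class TestStationNetwork:
    def test_single_station_inside_domain(self):
        cfg = hl.SimConfig(n_stations=1, seed=7)
        pts = synthetic.generate_station_network(cfg)
        assert pts.shape == (1, 2)
        assert np.all((pts >= 0) & (pts <= cfg.domain_km))

    def test_seeded_determinism(self):
        cfg = hl.SimConfig(n_stations=5, seed=7)
        a = synthetic.generate_station_network(cfg)
        b = synthetic.generate_station_network(cfg)
        assert np.array_equal(a, b)

    def test_thirteen_distinct_stations(self):
        cfg = hl.SimConfig(n_stations=13, seed=1)
        pts = synthetic.generate_station_network(cfg)
        assert pts.shape == (13, 2)
        assert len({tuple(p) for p in pts}) == 13

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            hl.SimConfig(n_stations=0)
        with pytest.raises(ValueError):
            hl.SimConfig(domain_km=-1.0)


class TestWeatherGeneration:
    def test_degenerate_constant_series(self):
        cfg = hl.SimConfig(
            n_stations=2, years=(2014,), seasonal_amplitude=0.0,
            noise_sd=0.0, missing_rate=0.0, seed=3,
        )
        wx = synthetic.generate_weather(cfg, synthetic.generate_station_network(cfg))
        assert np.allclose(wx.true_temperature, cfg.seasonal_mean)

    def test_ar1_autocorrelation_matches_rho(self):
        cfg = hl.SimConfig(
            n_stations=2, years=tuple(range(2008, 2018)),
            seasonal_amplitude=0.0, ar1_rho=0.7, noise_sd=1.0,
            missing_rate=0.0, seed=9,
        )
        wx = synthetic.generate_weather(cfg, synthetic.generate_station_network(cfg))
        x = wx.true_temperature[0] - cfg.seasonal_mean
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1 - 0.7) < 0.1

    def test_missing_rate_recovered(self):
        cfg = hl.SimConfig(
            n_stations=3, years=(2012, 2013, 2014), missing_rate=0.1, seed=4
        )
        wx = synthetic.generate_weather(cfg, synthetic.generate_station_network(cfg))
        mask = np.concatenate([s.mask for s in wx.temperature])
        assert mask.size >= 3000
        assert abs(mask.mean() - 0.1) < 0.02

    def test_humidity_clipped_to_physical_range(self):
        cfg = hl.SimConfig(n_stations=2, years=(2014,), rh_sd=40.0,
                           missing_rate=0.0, seed=2)
        wx = synthetic.generate_weather(cfg, synthetic.generate_station_network(cfg))
        assert wx.true_humidity.min() >= 5.0
        assert wx.true_humidity.max() <= 100.0


class TestPopulation:
    def test_empty_population(self):
        cfg = hl.SimConfig(n_subjects=0, seed=1)
        assert len(synthetic.generate_population(cfg)) == 0

    def test_older_fraction(self):
        cfg = hl.SimConfig(n_subjects=10_000, seed=1)
        pop = synthetic.generate_population(cfg)
        assert abs((pop["age_group"] == "65+").mean() - 0.7) < 0.02
        assert abs((pop["sex"] == "F").mean() - 0.5) < 0.02

    def test_roster_determinism(self):
        cfg = hl.SimConfig(n_subjects=50, seed=5)
        a = synthetic.generate_population(cfg)
        b = synthetic.generate_population(cfg)
        pd.testing.assert_frame_equal(a, b)


class TestDeaths:
    @pytest.fixture()
    def tiny_world(self):
        cfg = hl.SimConfig(
            n_stations=2, n_subjects=200, years=(2014,),
            baseline_daily_hazard=5e-3, missing_rate=0.0, seed=21,
        )
        cal = cfg.calendar
        rng = np.random.default_rng(0)
        hw = rng.random((200, len(cal))) < 0.05
        hw[:, :6] = False  # no pre-study heat-wave history
        return cfg, cal, hw

    def test_zero_hazard_means_zero_deaths(self, tiny_world):
        cfg, cal, hw = tiny_world
        cfg = cfg.replace(baseline_daily_hazard=0.0)
        pop = synthetic.generate_population(cfg)
        deaths, _ = synthetic.generate_deaths(cfg, pop, hw, cal)
        assert deaths.empty

    def test_hazard_at_least_one_rejected(self, tiny_world):
        cfg, cal, hw = tiny_world
        cfg = cfg.replace(baseline_daily_hazard=0.9, true_cum_log_or=np.log(3.0))
        pop = synthetic.generate_population(cfg)
        with pytest.raises(ValueError, match="hazard"):
            synthetic.generate_deaths(cfg, pop, hw, cal)

    def test_null_effect_ignores_heat_waves(self, tiny_world):
        # with a zero effect the sampled deaths are identical whatever the
        # heat-wave history, because the hazard does not depend on it
        cfg, cal, hw = tiny_world
        cfg = cfg.replace(true_cum_log_or=0.0)
        pop = synthetic.generate_population(cfg)
        d1, _ = synthetic.generate_deaths(cfg, pop, hw, cal)
        d2, _ = synthetic.generate_deaths(cfg, pop, np.zeros_like(hw), cal)
        pd.testing.assert_frame_equal(d1, d2)

    def test_single_lag_weight_shifts_dependence(self, tiny_world):
        # concentrating all weight on lag 2 makes the hazard a function of
        # HW[t-2] alone: feeding an indicator advanced by 2 days yields the
        # identical hazard sequence, hence the identical death pattern
        # (and the injected cumulative log OR is unchanged)
        cfg, cal, hw = tiny_world
        w0 = np.zeros(6); w0[0] = 1.0
        w2 = np.zeros(6); w2[2] = 1.0
        pop = synthetic.generate_population(cfg)
        hw_shifted = np.zeros_like(hw)
        hw_shifted[:, :-2] = hw[:, 2:]
        d0, gt0 = synthetic.generate_deaths(
            cfg.replace(lag_weights=w0), pop, hw, cal
        )
        d2, gt2 = synthetic.generate_deaths(
            cfg.replace(lag_weights=w2), pop, hw_shifted, cal
        )
        assert gt0.true_cum_log_or == gt2.true_cum_log_or
        pd.testing.assert_frame_equal(d0, d2)

    def test_cause_split(self):
        cfg = hl.SimConfig(
            n_stations=2, n_subjects=20_000, years=(2014,),
            baseline_daily_hazard=5e-3, missing_rate=0.0, seed=8,
        )
        pop = synthetic.generate_population(cfg)
        hw = np.zeros((20_000, len(cfg.calendar)), dtype=bool)
        deaths, _ = synthetic.generate_deaths(cfg, pop, hw, cfg.calendar)
        assert len(deaths) > 3000
        assert abs((deaths["cause"] == "cardiovascular").mean() - 0.69) < 0.03

    def test_deaths_deterministic(self, tiny_world):
        cfg, cal, hw = tiny_world
        pop = synthetic.generate_population(cfg)
        d1, _ = synthetic.generate_deaths(cfg, pop, hw, cal)
        d2, _ = synthetic.generate_deaths(cfg, pop, hw, cal)
        pd.testing.assert_frame_equal(d1, d2)

    def test_first_event_only(self, tiny_world):
        cfg, cal, hw = tiny_world
        pop = synthetic.generate_population(cfg)
        deaths, _ = synthetic.generate_deaths(cfg, pop, hw, cal)
        assert deaths["subject_id"].is_unique


def test_lag_weights_validated():
    with pytest.raises(ValueError, match="lag_weights"):
        hl.SimConfig(lag_weights=np.array([0.5, 0.4]))
    with pytest.raises(ValueError, match="ar1_rho"):
        hl.SimConfig(ar1_rho=1.0)
    with pytest.raises(ValueError, match="missing_rate"):
        hl.SimConfig(missing_rate=0.25)


def test_one_station_exposure_equals_station_series():
    # pipeline property: a single station and any IDW parameters reproduce
    # that station's series at every point of the domain
    from heatlag import exposure

    cfg = hl.SimConfig(n_stations=1, years=(2014,), missing_rate=0.0, seed=6)
    net = synthetic.generate_station_network(cfg)
    wx = synthetic.generate_weather(cfg, net)
    target = np.array([[3.0, 17.0]])
    for p in (1.0, 2.5):
        W = exposure.idw_matrix(target, net, exposure.IdwParams(p, 1))
        pred = W @ wx.true_temperature
        assert np.allclose(pred[0], wx.true_temperature[0])
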