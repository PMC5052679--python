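"""Oxygen solubility, gas exchange, water balance and the NEM inversion."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from saltmarsh.nem import (
    GAS_EXCHANGE_MODELS,
    CreekGeometry,
    GasExchangeModel,
    NEMResult,
    apply_bias_correction,
    creek_difference,
    gas_exchange_flux,
    high_tide_means,
    nem_series,
    o2_saturation_concentration,
    water_balance,
)
from saltmarsh.synthetic import CreekSimConfig, simulate_tidal_creek
from saltmarsh.tables import TidalCreekSeries

NO_GAS = GasExchangeModel("none", wind_coef=0.0, current_coef=0.0)


def _oracle_o2_umol_kg(t, s):
    """Independently coded solubility polynomial (combined Benson-Krause
    fit), kept separate from the implementation on purpose."""
    ts = np.log((298.15 - t) / (273.15 + t))
    a = [5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369]
    b = [-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3]
    poly_a = sum(a[i] * ts**i for i in range(6))
    poly_b = sum(b[i] * ts**i for i in range(4))
    return np.exp(poly_a + s * poly_b + (-2.75915e-7) * s**2)


class TestSolubility:
    def test_matches_published_check_value(self):
        # the combined fit's check point: T=10, S=35 -> 274.61 umol/kg
        got = o2_saturation_concentration(10.0, 35.0, unit="umol_kg")
        assert got == pytest.approx(274.61, rel=5e-5)
        assert got == pytest.approx(_oracle_o2_umol_kg(10.0, 35.0), rel=1e-12)

    def test_monotone_decreasing_in_t_and_s(self):
        t = np.linspace(0, 35, 30)
        c_t = o2_saturation_concentration(t, 30.0)
        assert np.all(np.diff(c_t) < 0)
        s = np.linspace(0, 40, 30)
        c_s = o2_saturation_concentration(15.0, s)
        assert np.all(np.diff(c_s) < 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            o2_saturation_concentration(45.0, 30.0)
        with pytest.raises(ValueError):
            o2_saturation_concentration(10.0, 43.0)

    def test_volumetric_and_mass_units_consistent(self):
        # mmol/m3 ~= umol/kg x seawater density (~1.02 kg/L)
        ratio = (o2_saturation_concentration(10, 35)
                 / o2_saturation_concentration(10, 35, unit="umol_kg"))
        assert 1.0 < ratio < 1.05


class TestGasExchange:
    def test_k_nonnegative_and_monotone(self):
        model = GAS_EXCHANGE_MODELS["wind_current"]
        winds = np.linspace(0, 15, 20)
        ks = model.k(winds, 0.2, 1.0)
        assert np.all(ks >= 0) and np.all(np.diff(ks) >= 0)
        currents = np.linspace(0, 1.5, 20)
        ks = model.k(3.0, currents, 1.0)
        assert np.all(np.diff(ks) >= 0)

    def test_single_term_models_are_smaller(self):
        full = GAS_EXCHANGE_MODELS["wind_current"].k(4.0, 0.3, 1.0)
        assert GAS_EXCHANGE_MODELS["wind_only"].k(4.0, 0.3, 1.0) < full
        assert GAS_EXCHANGE_MODELS["current_only"].k(4.0, 0.3, 1.0) < full

    def test_flux_sign_convention(self):
        geom = CreekGeometry()
        model = GAS_EXCHANGE_MODELS["wind_current"]
        assert gas_exchange_flux(model, 3, 0.2, 1.0, 250.0, 250.0, geom) == 0.0
        assert gas_exchange_flux(model, 3, 0.2, 1.0, 300.0, 250.0, geom) < 0
        assert gas_exchange_flux(model, 3, 0.2, 1.0, 200.0, 250.0, geom) > 0

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            GAS_EXCHANGE_MODELS["wind_current"].k(1.0, 0.1, 0.0)


class TestWaterBalance:
    def test_constant_depth_no_flux(self):
        v, dvdt, q = water_balance(np.full(20, 1.3), 10.0, CreekGeometry())
        assert np.allclose(dvdt, 0) and np.allclose(q, 0)

    def test_rectangular_channel_closed_form(self):
        geom = CreekGeometry(bottom_width=4.0, bank_slope=0.0)
        t = np.arange(50) * 10.0
        h = 1.0 + 0.5 * np.sin(t / 200.0)
        v, dvdt, _ = water_balance(h, 10.0, geom)
        assert np.allclose(v, 4.0 * h)
        assert np.allclose(dvdt, 4.0 * np.gradient(h, 10.0))

    def test_trapezoid_volume_matches_quadrature(self):
        geom = CreekGeometry(bottom_width=2.5, bank_slope=1.7)
        for h in (0.3, 1.0, 2.4):
            integral, _ = quad(lambda z: geom.width(z), 0.0, h)
            assert geom.volume(h) == pytest.approx(integral, abs=1e-9)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            water_balance(np.array([1.0, -0.1]), 10.0, CreekGeometry())


def _constant_series(n, depth=1.0, conc=None, sat=None, step="10min"):
    idx = pd.date_range("2012-08-01", periods=n, freq=step)
    cols = {"depth": depth, "temperature": 20.0, "salinity": 30.0,
            "wind": 0.0, "current": 0.0}
    if conc is not None:
        cols["o2_concentration"] = conc
    else:
        cols["o2_saturation"] = 100.0 if sat is None else sat
    return TidalCreekSeries(pd.DataFrame(cols, index=idx))


class TestNemSeries:
    def test_closed_system_conservation(self):
        # dV/dt = 0, k = 0, C falling 1 mmol m^-3 min^-1 in V = 10 m^3 m^-1
        geom = CreekGeometry(bottom_width=10.0, bank_slope=0.0)
        n = 30
        conc = 300.0 - 1.0 * np.arange(n) * 10.0
        series = _constant_series(n, depth=1.0, conc=conc)
        res = nem_series(series, geom, NO_GAS)
        assert np.allclose(res.nem, -10.0)

    def test_steady_state_at_saturation_is_zero(self):
        res = nem_series(_constant_series(30), CreekGeometry(),
                         GAS_EXCHANGE_MODELS["wind_current"])
        assert np.allclose(res.nem, 0.0, atol=1e-9)

    def test_budget_identity(self):
        series, _ = simulate_tidal_creek(CreekSimConfig(seed=1, noise_sd=0.5))
        res = nem_series(series, CreekGeometry())
        lhs = res.series["nem"] + res.series["advective"] + res.series["gas_flux"]
        scale = np.abs(res.series["storage"]).max()
        assert np.allclose(lhs, res.series["storage"], atol=1e-9 * scale)

    def test_forward_inverse_recovery(self):
        cfg = CreekSimConfig(days=3.0, seed=2, noise_sd=0.0)
        series, truth = simulate_tidal_creek(cfg)
        res = nem_series(series, CreekGeometry())
        err = res.nem.to_numpy() - truth["nem"].to_numpy()
        rmse = np.sqrt(np.mean(err**2))
        assert rmse < 0.05 * np.ptp(truth["nem"].to_numpy())

    def test_recovery_robust_across_k_scales(self):
        for k_scale in (0.0, 1.0, 3.0):
            cfg = CreekSimConfig(days=2.0, seed=3, k_scale=k_scale)
            series, truth = simulate_tidal_creek(cfg, gas_model="wind_current")
            res = nem_series(series, CreekGeometry())
            if k_scale != 1.0:
                # estimator must use the same k scaling as the forward model
                model = GasExchangeModel("scaled",
                                         wind_coef=0.266 * k_scale,
                                         current_coef=0.77 * k_scale)
                res = nem_series(series, CreekGeometry(), model)
            err = res.nem.to_numpy() - truth["nem"].to_numpy()
            assert np.sqrt(np.mean(err**2)) < 0.05 * np.ptp(truth["nem"])

    def test_pure_respiration_is_negative(self):
        cfg = CreekSimConfig(days=2.0, production_amplitude=0.0, seed=4)
        series, _ = simulate_tidal_creek(cfg)
        res = nem_series(series, CreekGeometry())
        assert np.all(res.nem.to_numpy() < 0)

    def test_dt_refinement_invariance(self):
        # halving the evaluation step changes the recovered NEM by < 1%
        cfg = CreekSimConfig(days=2.0, dt_minutes=5.0, seed=5)
        series, truth = simulate_tidal_creek(cfg)
        res5 = nem_series(series, CreekGeometry(), dt_eval_minutes=5.0)
        res10 = nem_series(series, CreekGeometry(), dt_eval_minutes=10.0)
        common = res10.series.index
        scale = np.ptp(truth["nem"].to_numpy())
        diff = res5.series.loc[common, "nem"] - res10.series["nem"]
        assert np.abs(diff).max() < 0.01 * scale

    def test_dt_eval_must_divide_series_step(self):
        series, _ = simulate_tidal_creek(CreekSimConfig(days=1.0, seed=0))
        with pytest.raises(ValueError):
            nem_series(series, CreekGeometry(), dt_eval_minutes=15.0)


class TestHighTideWindows:
    def test_six_days_semidiurnal_gives_twelve_windows(self):
        series, _ = simulate_tidal_creek(CreekSimConfig(seed=6))
        res = nem_series(series, CreekGeometry())
        windows = high_tide_means(res)
        assert len(windows) == 12
        assert (windows["n"] == 7).all()  # 60-min window at 10-min sampling

    def test_constant_nem_zero_sd(self):
        # saturated steady tide-free water: NEM identically 0, sd 0
        res = nem_series(_constant_series(40), CreekGeometry(), NO_GAS)
        # inject an artificial single peak in depth
        res.series.loc[res.series.index[20], "depth"] += 0.5
        windows = high_tide_means(res)
        assert len(windows) == 1
        assert windows["sd_nem"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_flag_fires_iff_peak_exceeds_platform(self):
        series, _ = simulate_tidal_creek(CreekSimConfig(seed=7))
        res = nem_series(series, CreekGeometry(platform_elevation=1.8))
        windows = high_tide_means(res)
        assert (windows["peak_flood_bias"] ==
                (windows["peak_depth"] > 1.8)).all()
        assert windows["peak_flood_bias"].any()
        assert not windows["peak_flood_bias"].all()

    def test_truncated_window_dropped_with_warning(self):
        series, _ = simulate_tidal_creek(CreekSimConfig(days=1.0, seed=8))
        res = nem_series(series, CreekGeometry())
        # chop the record so the first peak sits at the boundary
        peak_pos = int(np.argmax(res.series["depth"].to_numpy()[:80]))
        res.series = res.series.iloc[peak_pos - 1:]
        with pytest.warns(UserWarning, match="truncated"):
            windows = high_tide_means(res)
        assert len(windows) < 2


class TestCreekDifference:
    def _paired_results(self, scale=1.0, seed=9):
        cfg = CreekSimConfig(seed=seed)
        ref, _ = simulate_tidal_creek(cfg)
        enr, _ = simulate_tidal_creek(cfg, production_scale=scale,
                                      respiration_scale=scale)
        res_r = nem_series(ref, CreekGeometry())
        res_e = nem_series(enr, CreekGeometry())
        high_tide_means(res_r)
        high_tide_means(res_e)
        return res_e, res_r

    def test_identical_creeks_zero_difference(self):
        res_e, res_r = self._paired_results(scale=1.0)
        diff = creek_difference(res_e, res_r)
        assert np.allclose(diff["diff_mean_nem"], 0.0, atol=1e-12)

    def test_constant_shift_recovered(self):
        res_e, res_r = self._paired_results(scale=1.0)
        res_e.windows["mean_nem"] += 0.25
        diff = creek_difference(res_e, res_r)
        assert np.allclose(diff["diff_mean_nem"], 0.25)

    def test_amplified_metabolism_day_night_pattern(self):
        res_e, res_r = self._paired_results(scale=1.5)
        diff = creek_difference(res_e, res_r)
        hours = diff["center"].dt.hour + diff["center"].dt.minute / 60.0
        day = (hours >= 8) & (hours <= 16)
        night = (hours <= 4) | (hours >= 20)
        assert diff.loc[day, "diff_mean_nem"].mean() > 0
        assert diff.loc[night, "diff_mean_nem"].mean() < 0

    def test_unmatched_window_counts_rejected(self):
        res_e, res_r = self._paired_results()
        res_e.windows = res_e.windows.iloc[:-1]
        with pytest.raises(ValueError, match="unmatched"):
            creek_difference(res_e, res_r)


class TestBiasCorrection:
    def _result_with_windows(self):
        series, _ = simulate_tidal_creek(CreekSimConfig(seed=10))
        res = nem_series(series, CreekGeometry(platform_elevation=1.8))
        high_tide_means(res)
        return res

    def test_zero_bias_is_identity(self):
        res = self._result_with_windows()
        before = res.windows["mean_nem"].copy()
        out = apply_bias_correction(res, 0.0)
        assert np.allclose(out.windows["mean_nem"], before)

    def test_flagged_windows_reduced_by_exact_bias(self):
        res = self._result_with_windows()
        before = res.windows["mean_nem"].copy()
        out = apply_bias_correction(res, 0.35)
        flagged = out.windows["peak_flood_bias"]
        assert np.allclose(out.windows.loc[flagged, "mean_nem"],
                           before[flagged] - 0.35)
        assert np.allclose(out.windows.loc[~flagged, "mean_nem"],
                           before[~flagged])
        assert any("0.35" in note for note in out.notes)

    def test_negative_bias_rejected(self):
        res = self._result_with_windows()
        with pytest.raises(ValueError):
            apply_bias_correction(res, -0.1)
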