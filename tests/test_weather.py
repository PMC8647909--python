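"""Weather QC, gap filling and derived daily variables."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from gxemet import weather as wx


def _subdaily(date="2015-06-01", **series):
    """Build a long-format day of 48 records per variable."""
    ts = pd.Timestamp(date) + pd.to_timedelta(np.arange(48) * 0.5, unit="h")
    rows = []
    for var, vals in series.items():
        vals = np.broadcast_to(np.asarray(vals, float), (48,))
        rows += [(t, var, v) for t, v in zip(ts, vals)]
    return pd.DataFrame(rows, columns=["timestamp", "variable", "value"])


class TestQCAggregate:
    def test_clean_day_aggregates_without_flags(self):
        temp = 18 + 6 * np.sin(np.linspace(0, 2 * np.pi, 48, endpoint=False))
        rec = _subdaily(temperature=temp, rh=60.0 + np.linspace(0, 1, 48), rainfall=0.2, wind=2.0 + np.linspace(0, 0.5, 48))
        day = wx.qc_aggregate_daily(rec).iloc[0]
        assert not any(day[f"flag_{f}"] for f in wx.QC_FLAGS)
        assert day["tmax"] == pytest.approx(temp.max())
        assert day["tmin"] == pytest.approx(temp.min())
        assert day["tmean"] == pytest.approx((temp.max() + temp.min()) / 2)
        assert day["precip"] == pytest.approx(0.2 * 48)
        assert day["rh"] == pytest.approx(60.5, abs=0.1)

    def test_stuck_sensor_sets_persistence_flag_and_missing(self):
        rec = _subdaily(temperature=21.0, rh=60.0 + np.linspace(0, 1, 48))
        day = wx.qc_aggregate_daily(rec).iloc[0]
        assert day["flag_persistence"]
        assert np.isnan(day["tmax"]) and np.isnan(day["tmin"])
        assert np.isfinite(day["rh"])  # unaffected variable survives

    def test_out_of_range_spike_flags_range(self):
        temp = 18 + 6 * np.sin(np.linspace(0, 2 * np.pi, 48, endpoint=False))
        temp[10] = 80.0
        day = wx.qc_aggregate_daily(_subdaily(temperature=temp)).iloc[0]
        assert day["flag_range"] and np.isnan(day["tmax"])

    def test_too_few_records_flags_count(self):
        temp = 18 + 6 * np.sin(np.linspace(0, 2 * np.pi, 48, endpoint=False))
        rec = _subdaily(temperature=temp).iloc[:30]  # 30 < 0.8 * 48
        day = wx.qc_aggregate_daily(rec).iloc[0]
        assert day["flag_count"] and np.isnan(day["tmax"])

    def test_daily_input_consistency_check(self):
        # already-daily input with tmin > tmax must be flagged inconsistent
        rec = pd.DataFrame(
            {
                "timestamp": [pd.Timestamp("2015-06-01")] * 2,
                "variable": ["tmax", "tmin"],
                "value": [15.0, 20.0],
            }
        )
        day = wx.qc_aggregate_daily(rec, wx.QCConfig(records_per_day=1)).iloc[0]
        assert day["flag_consistency"]
        assert np.isnan(day["tmax"])

    def test_idempotent_on_daily_input(self):
        rec = pd.DataFrame(
            {
                "timestamp": [pd.Timestamp("2015-06-01")] * 4,
                "variable": ["tmax", "tmin", "precip", "rh"],
                "value": [25.0, 14.0, 3.0, 62.0],
            }
        )
        day = wx.qc_aggregate_daily(rec, wx.QCConfig(records_per_day=1)).iloc[0]
        assert day["tmax"] == 25.0 and day["tmin"] == 14.0
        assert day["tmean"] == pytest.approx(19.5)
        assert day["precip"] == 3.0 and day["rh"] == 62.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            wx.qc_aggregate_daily(pd.DataFrame(columns=["timestamp", "variable", "value"]))


class TestIDW:
    def _daily(self, values, start="2015-06-01"):
        idx = pd.date_range(start, periods=len(values), freq="D")
        df = pd.DataFrame(index=idx, columns=wx.DAILY_VARS, dtype=float)
        df["tmax"] = values
        for f in wx.QC_FLAGS:
            df[f"flag_{f}"] = False
        return df

    def test_single_neighbor_copies_value(self):
        target = self._daily([np.nan, 25.0])
        nb = self._daily([20.0, 21.0])
        out = wx.fill_gaps_idw(target, [(nb, 10.0)])
        assert out["tmax"].iloc[0] == 20.0
        assert out["flag_imputed"].iloc[0]
        assert out["tmax"].iloc[1] == 25.0  # observed untouched

    def test_equidistant_neighbors_average(self):
        target = self._daily([np.nan])
        out = wx.fill_gaps_idw(target, [(self._daily([10.0]), 5.0), (self._daily([20.0]), 5.0)])
        assert out["tmax"].iloc[0] == pytest.approx(15.0)

    def test_weights_follow_inverse_square_distance(self):
        target = self._daily([np.nan])
        nbs = [(self._daily([v]), d) for v, d in [(10.0, 1.0), (20.0, 2.0), (30.0, 4.0)]]
        out = wx.fill_gaps_idw(target, nbs, power=2.0)
        w = np.array([1.0, 0.25, 0.0625])
        expected = (w * np.array([10.0, 20.0, 30.0])).sum() / w.sum()
        assert out["tmax"].iloc[0] == pytest.approx(expected)

    def test_no_coverage_stays_missing(self):
        target = self._daily([np.nan])
        nb = self._daily([np.nan])
        out = wx.fill_gaps_idw(target, [(nb, 3.0)])
        assert np.isnan(out["tmax"].iloc[0])


class TestGrowingDegrees:
    @pytest.mark.parametrize(
        "tmin,tmax,expected",
        [(12.0, 20.0, 6.0), (2.0, 8.0, 0.0), (10.0, 10.0, 0.0)],
    )
    def test_closed_form_regions(self, tmin, tmax, expected):
        assert wx.daily_growing_degrees(tmin, tmax) == pytest.approx(expected)

    def test_sine_interpolation_matches_quadrature(self):
        tmin, tmax, base = 4.0, 16.0, 10.0
        mean, w = (tmax + tmin) / 2, (tmax - tmin) / 2

        def temp(hours):
            return mean + w * np.sin(2 * np.pi * hours / 24.0)

        oracle = quad(lambda h: max(temp(h) - base, 0.0), 0, 24)[0] / 24.0
        assert wx.daily_growing_degrees(tmin, tmax, base) == pytest.approx(oracle, abs=1e-3)

    def test_continuous_across_base_crossing(self):
        # approaching tmin == base from below and above must agree
        lo = wx.daily_growing_degrees(10.0 - 1e-7, 20.0)
        hi = wx.daily_growing_degrees(10.0 + 1e-7, 20.0)
        assert lo == pytest.approx(hi, abs=1e-5)
        lo = wx.daily_growing_degrees(4.0, 10.0 - 1e-7)
        assert lo == pytest.approx(0.0, abs=1e-4)

    def test_rejects_inverted_temperatures(self):
        with pytest.raises(ValueError):
            wx.daily_growing_degrees(21.0, 20.0)


class TestDayLength:
    def test_equator_near_twelve_hours(self):
        for doy in (1, 100, 200, 300):
            assert wx.day_length(0.0, doy) == pytest.approx(12.0, abs=0.2)

    def test_equinox_symmetry(self):
        assert wx.day_length(45.0, 80) == pytest.approx(12.0, abs=0.3)

    def test_matches_independent_solar_geometry(self):
        # Spencer's Fourier-series declination as an independent route
        def oracle(lat, doy):
            g = 2 * np.pi / 365.0 * (doy - 1)
            decl = (
                0.006918
                - 0.399912 * np.cos(g)
                + 0.070257 * np.sin(g)
                - 0.006758 * np.cos(2 * g)
                + 0.000907 * np.sin(2 * g)
                - 0.002697 * np.cos(3 * g)
                + 0.00148 * np.sin(3 * g)
            )
            ws = np.arccos(-np.tan(np.radians(lat)) * np.tan(decl))
            return 24.0 / np.pi * ws

        assert wx.day_length(45.0, 172) == pytest.approx(oracle(45.0, 172), abs=0.05)

    def test_polar_unsupported(self):
        with pytest.raises(ValueError):
            wx.day_length(70.0, 172)


def test_photothermal_time_is_product_and_additive():
    assert wx.photothermal_time(0.0, 14.0) == 0.0
    assert wx.photothermal_time(6.0, 15.0) == pytest.approx(90.0)
    gdd = np.array([3.0, 5.0, 7.0])
    dl = np.array([14.0, 14.5, 15.0])
    assert wx.photothermal_time(gdd, dl).sum() == pytest.approx(sum(g * d for g, d in zip(gdd, dl)))
    with pytest.raises(ValueError):
        wx.photothermal_time(-1.0, 12.0)


class TestVPD:
    def test_saturated_air_has_zero_deficit(self):
        assert wx.vapor_pressure_deficit(15.0, 25.0, 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_dry_air_equals_saturation_pressure(self):
        es = (wx.saturation_vapor_pressure(25.0) + wx.saturation_vapor_pressure(15.0)) / 2
        assert wx.vapor_pressure_deficit(15.0, 25.0, 0.0) == pytest.approx(es)

    def test_hand_computed_tetens(self):
        es25 = 0.6108 * np.exp(17.27 * 25 / (25 + 237.3))
        es15 = 0.6108 * np.exp(17.27 * 15 / (15 + 237.3))
        expected = (es25 + es15) / 2 * (1 - 0.60)
        assert wx.vapor_pressure_deficit(15.0, 25.0, 60.0) == pytest.approx(expected, abs=1e-3)

    def test_invalid_humidity_rejected(self):
        with pytest.raises(ValueError):
            wx.vapor_pressure_deficit(15.0, 25.0, 120.0)


def _et0_oracle(tmin, tmax, rh, u2, rs, lat, z, doy):
    """Independently coded FAO-56 Penman-Monteith (step-by-step arrangement)."""
    t = 0.5 * (tmin + tmax)
    e0 = lambda T: 0.6108 * np.exp(17.27 * T / (T + 237.3))
    es = 0.5 * (e0(tmin) + e0(tmax))
    ea = rh / 100.0 * es
    slope = 4098.0 * e0(t) / (t + 237.3) ** 2
    press = 101.3 * ((293.0 - 0.0065 * z) / 293.0) ** 5.26
    psy = 0.665e-3 * press
    phi = np.radians(lat)
    dr = 1 + 0.033 * np.cos(2 * np.pi * doy / 365)
    dec = 0.409 * np.sin(2 * np.pi * doy / 365 - 1.39)
    ws = np.arccos(-np.tan(phi) * np.tan(dec))
    ra = (24 * 60 / np.pi) * 0.082 * dr * (
        ws * np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.sin(ws)
    )
    rso = (0.75 + 2e-5 * z) * ra
    rns = 0.77 * rs
    tk4 = ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2
    rnl = 4.903e-9 * tk4 * (0.34 - 0.14 * np.sqrt(ea)) * (1.35 * min(rs / rso, 1.0) - 0.35)
    rn = rns - rnl
    num = 0.408 * slope * rn + psy * (900.0 / (t + 273.0)) * u2 * (es - ea)
    return max(num / (slope + psy * (1 + 0.34 * u2)), 0.0)


class TestET0:
    def test_matches_independent_implementation(self):
        args = dict(tmin=16.0, tmax=28.0, rh=60.0, u2=2.0, rs=24.0, lat=42.0, z=200.0, doy=190)
        got = wx.et0_fao56(args["tmin"], args["tmax"], args["rh"], args["u2"], args["rs"],
                           args["lat"], args["z"], args["doy"])
        assert got == pytest.approx(_et0_oracle(**args), abs=0.05)
        assert got > 0

    def test_nondecreasing_in_wind_with_positive_vpd(self):
        vals = [
            wx.et0_fao56(14.0, 26.0, 50.0, u, 22.0, 42.0, 200.0, 180) for u in (0.5, 1.5, 3.0, 5.0)
        ]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_no_drivers_no_evaporation(self):
        # zero vpd (saturated air), no wind, no shortwave, and air warm
        # enough that the longwave emissivity factor 0.34 - 0.14 sqrt(ea)
        # vanishes: the radiation balance and the aerodynamic term are
        # both zero, so reference evapotranspiration must be zero
        from scipy.optimize import brentq

        t0 = brentq(
            lambda t: 0.34 - 0.14 * np.sqrt(wx.saturation_vapor_pressure(t)), 20.0, 45.0
        )
        got = wx.et0_fao56(t0, t0, 100.0, 0.0, 0.0, 42.0, 200.0, 180)
        assert got == pytest.approx(0.0, abs=1e-6)


def test_daily_water_balance_signs_and_additivity():
    assert wx.daily_water_balance(10.0, 4.0) == pytest.approx(6.0)
    assert wx.daily_water_balance(0.0, 5.0) == pytest.approx(-5.0)
    p = np.array([2.0, 0.0, 8.0])
    e = np.array([4.0, 5.0, 3.0])
    assert wx.daily_water_balance(p, e).sum() == pytest.approx(p.sum() - e.sum())
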