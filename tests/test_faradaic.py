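"""Charge integration, Faraday's-law mass conversion, anode localisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sczra.corrosion import CorrosionRate
from sczra.faradaic import (FARADAY, FaradayParams, faraday_mass,
                            infer_net_anode, integrate_charge,
                            predicted_biotic_rate, prediction_accuracy)
from sczra.io import CouponRecord, ElectrochemTrace


def _trace(time_h, current_A):
    time_h = np.asarray(time_h, float)
    return ElectrochemTrace(time_h, np.asarray(current_A, float),
                            np.full_like(time_h, -0.68))


def _grid(hours, dt=0.25):
    return np.arange(0.0, hours + dt / 2, dt)


class TestIntegrateCharge:
    def test_constant_current_rectangle(self):
        t = _grid(10.0)
        s = integrate_charge(_trace(t, np.full_like(t, 2e-3)))
        assert s.total == pytest.approx(2e-3 * 10 * 3600, rel=1e-12)
        assert s.negative == 0.0

    def test_linear_ramp_triangle(self):
        t = _grid(1.0)
        s = integrate_charge(_trace(t, 1e-3 * t))  # 0 -> 1 mA over 1 h
        assert s.total == pytest.approx(0.5 * 1e-3 * 3600, rel=1e-12)

    def test_slow_sine_matches_analytic(self):
        # half period of a 1440-h sine sampled every 15 min
        t = _grid(720.0)
        omega = np.pi / 720.0  # rad per hour
        s = integrate_charge(_trace(t, 1e-3 * np.sin(omega * t)))
        exact = 1e-3 * 2.0 / (omega / 3600.0)
        assert s.total == pytest.approx(exact, rel=1e-6)

    def test_symmetric_square_wave_cancels(self):
        t = _grid(4.0)
        i = np.where((t % 2.0) < 1.0, 1e-3, -1e-3)
        s = integrate_charge(_trace(t, i))
        assert s.positive == pytest.approx(-s.negative, rel=1e-6)
        assert abs(s.total) < abs(s.positive) * 1e-6 + 1e-12

    def test_sign_partition_sums_to_total(self):
        rng = np.random.default_rng(7)
        t = _grid(24.0)
        s = integrate_charge(_trace(t, rng.normal(0, 1e-4, t.size)))
        assert s.total == pytest.approx(s.positive + s.negative, rel=1e-12)
        assert s.positive >= 0 >= s.negative

    def test_window_selection_and_bounds(self):
        t = _grid(10.0)
        tr = _trace(t, np.full_like(t, 1e-3))
        s = integrate_charge(tr, window=(2.0, 5.0))
        assert s.total == pytest.approx(1e-3 * 3 * 3600, rel=1e-12)
        with pytest.raises(ValueError, match="window"):
            integrate_charge(tr, window=(2.0, 11.0))

    def test_irregular_spacing_is_exact_for_linear_current(self):
        t = np.array([0.0, 0.1, 0.45, 1.0, 2.5])
        tr = _trace(t, 2e-3 * t)  # linear ramp -> trapezoid exact
        s = integrate_charge(tr)
        assert s.total == pytest.approx(0.5 * 2e-3 * 2.5 * 2.5 * 3600, rel=1e-12)


class TestFaradayMass:
    def test_zero_charge_zero_mass(self):
        assert faraday_mass(0.0) == 0.0

    def test_two_faradays_dissolve_one_mole_iron(self):
        assert faraday_mass(2 * FARADAY) == pytest.approx(55.845, rel=1e-12)

    def test_one_milliamp_day(self):
        q = 1e-3 * 24 * 3600  # 86.4 C
        assert faraday_mass(q) == pytest.approx(86.4 * 55.845 / 192970.0, rel=1e-9)
        assert faraday_mass(q) == pytest.approx(0.02500, abs=5e-6)

    @given(q=st.floats(0, 1e6), n=st.integers(1, 4))
    @settings(max_examples=50, derandomize=True)
    def test_linear_in_charge_and_inverse_valence(self, q, n):
        p = FaradayParams(valence=n)
        assert faraday_mass(q, p) == pytest.approx(
            faraday_mass(1.0, p) * q, rel=1e-12, abs=1e-300)
        assert faraday_mass(q, p) * n == pytest.approx(
            faraday_mass(q, FaradayParams(valence=1)), rel=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FaradayParams(valence=0)
        with pytest.raises(ValueError):
            FaradayParams(atomic_mass=-1)


class TestPredictedRate:
    def _coupon(self):
        return CouponRecord("WE2", "UNS G10180", 6.52, 7.87, 25.0, [25.0], 720.0)

    def test_zero_current_zero_rate(self):
        t = _grid(720.0)
        rate, anode = predicted_biotic_rate(_trace(t, np.zeros_like(t)), self._coupon())
        assert rate.value == 0.0
        assert anode == "balanced"

    def test_constant_negative_current_chain(self):
        # -0.1 mA for 720 h: Q = -259.2 C -> 0.07501 g -> 0.1779 mm/yr (7.00 mpy)
        t = _grid(720.0)
        rate, anode = predicted_biotic_rate(_trace(t, np.full_like(t, -1e-4)),
                                            self._coupon())
        assert anode == "WE2"
        assert rate.value == pytest.approx(0.1779, abs=2e-4)
        assert rate.mpy == pytest.approx(7.00, abs=5e-3)

    def test_unit_conversion_commutes_with_chain(self):
        t = _grid(720.0)
        tr = _trace(t, np.full_like(t, -1e-4))
        mm, _ = predicted_biotic_rate(tr, self._coupon(), units="mm_per_yr")
        mpy, _ = predicted_biotic_rate(tr, self._coupon(), units="mpy")
        assert mpy.value == pytest.approx(mm.mpy, rel=1e-12)


class TestNetAnode:
    def test_sustained_negative_current_puts_anode_on_we2(self):
        t = _grid(720.0)
        assert infer_net_anode(_trace(t, np.full_like(t, -1e-4))) == "WE2"

    def test_sustained_positive_current_puts_anode_on_we1(self):
        t = _grid(720.0)
        assert infer_net_anode(_trace(t, np.full_like(t, 1e-4))) == "WE1"

    def test_zero_trace_is_balanced(self):
        t = _grid(720.0)
        assert infer_net_anode(_trace(t, np.zeros_like(t))) == "balanced"

    def test_threshold_scales_with_window(self):
        # |Q| = 0.72 C over 360 h; threshold 1 C/30 d scales to 0.5 C
        t = _grid(360.0)
        i = np.full_like(t, 0.72 / (360 * 3600))
        assert infer_net_anode(_trace(t, i)) == "WE1"
        assert infer_net_anode(_trace(t, i / 10)) == "balanced"


class TestPredictionAccuracy:
    @pytest.mark.parametrize("pred,actual,expected", [
        (1.0, 1.1, 90.9),   # buffered inoculated treatment
        (1.1, 1.3, 84.6),   # unbuffered inoculated treatment
    ])
    def test_reported_pairs(self, pred, actual, expected):
        acc = prediction_accuracy(CorrosionRate(pred, "mpy"),
                                  CorrosionRate(actual, "mpy"))
        assert round(acc, 1) == expected

    def test_perfect_agreement_is_100(self):
        r = CorrosionRate(1.3, "mpy")
        assert prediction_accuracy(r, r) == pytest.approx(100.0)

    def test_zero_actual_is_not_applicable(self):
        assert prediction_accuracy(CorrosionRate(0.2, "mpy"),
                                   CorrosionRate(0.0, "mpy")) is None

    def test_floored_at_zero(self):
        assert prediction_accuracy(CorrosionRate(10.0, "mpy"),
                                   CorrosionRate(1.0, "mpy")) == 0.0
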