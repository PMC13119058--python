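"""Polymer-mechanics primitives: WLC elasticity, torque and unit conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect

from pscloop import (CouplingModel, HatCurveModel, TorqueModel, WLCParams,
                     contour_length, force_to_torque, hat_extension,
                     template_length_bp, turns_rate_to_bp_rate,
                     wlc_extension_to_force, wlc_force_to_extension)


def bisection_extension_oracle(params: WLCParams, force: float) -> float:
    """Independent solver for the extensible Marko–Siggia interpolation:
    bisect the residual in the entropic fractional extension u."""
    if force == 0:
        return 0.0
    a = params.kT / params.persistence_length

    def resid(u):
        return a * (0.25 / (1 - u) ** 2 - 0.25 + u) - force

    u = bisect(resid, 0.0, 1 - 1e-12, xtol=1e-13)
    return (u + force / params.stretch_modulus) * params.contour_um


class TestContourLength:
    @pytest.mark.parametrize("bp, expected", [
        (48_502, 16.39),   # λ-DNA, prints as 16.4 µm full extension
        (0, 0.0),
        (12_667, 4.281),   # magnetic-tweezer center fragment
    ])
    def test_known_lengths(self, bp, expected):
        assert contour_length(bp) == pytest.approx(expected, abs=5e-3)

    def test_negative_bp_rejected(self):
        with pytest.raises(ValueError):
            contour_length(-1)

    def test_template_assembly(self):
        assert template_length_bp(12_667, 500) == 13_667


class TestWLC:
    def test_zero_force_zero_extension(self, wlc):
        assert wlc_force_to_extension(wlc, 0.0) == 0.0
        assert wlc_extension_to_force(wlc, 0.0) == 0.0

    def test_matches_bisection_oracle(self, wlc):
        for f in [0.1, 0.5, 2.0, 5.0, 20.0, 60.0]:
            assert wlc_force_to_extension(wlc, f) == pytest.approx(
                bisection_extension_oracle(wlc, f), rel=1e-9)

    def test_strictly_monotone_on_dense_grid(self, wlc):
        grid = np.linspace(1e-6, 60.0, 10_000)
        ext = wlc_force_to_extension(wlc, grid)
        assert np.all(np.diff(ext) > 0)

    def test_enthalpic_regime_exceeds_contour(self):
        p = WLCParams(force_cap=1e5)
        f = 10 * p.stretch_modulus
        assert wlc_force_to_extension(p, f) / p.contour_um > 1.0

    def test_round_trip_identity(self, wlc):
        forces = np.linspace(1e-3, 60.0, 200)
        ext = wlc_force_to_extension(wlc, forces)
        back = wlc_extension_to_force(wlc, ext)
        assert np.max(np.abs(back - forces)) < 1e-6

    def test_round_trip_at_2pn(self, wlc):
        x = wlc_force_to_extension(wlc, 2.0)
        assert wlc_extension_to_force(wlc, x) == pytest.approx(2.0, abs=1e-6)

    def test_extension_beyond_cap_rejected(self, wlc):
        cap = wlc_force_to_extension(wlc, wlc.force_cap)
        with pytest.raises(ValueError):
            wlc_extension_to_force(wlc, 1.1 * cap)

    def test_negative_inputs_rejected(self, wlc):
        with pytest.raises(ValueError):
            wlc_force_to_extension(wlc, -1.0)
        with pytest.raises(ValueError):
            wlc_extension_to_force(wlc, -1.0)

    @settings(derandomize=True, max_examples=30)
    @given(lp=st.floats(10, 100), k=st.floats(300, 2000),
           f=st.floats(0.01, 50))
    def test_round_trip_property(self, lp, k, f):
        p = WLCParams(persistence_length=lp, stretch_modulus=k)
        assert wlc_extension_to_force(
            p, wlc_force_to_extension(p, f)) == pytest.approx(f, abs=1e-6)


class TestTorqueConversion:
    def test_one_piconewton(self):
        assert force_to_torque(TorqueModel(), 1.0) == 12.7825

    def test_zero(self):
        assert force_to_torque(TorqueModel(), 0.0) == 0.0

    def test_two_piconewtons(self):
        assert force_to_torque(TorqueModel(), 2.0) == pytest.approx(19.84,
                                                                    abs=5e-3)

    def test_loglog_slope_is_exponent(self):
        m = TorqueModel()
        f = np.logspace(-1, 1.5, 50)
        slope = np.polyfit(np.log(f), np.log(force_to_torque(m, f)), 1)[0]
        assert slope == pytest.approx(m.exponent, abs=1e-9)

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            force_to_torque(TorqueModel(), -1.0)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            TorqueModel(coefficient=-1)
        with pytest.raises(ValueError):
            TorqueModel(exponent=1.5)


class TestCouplingConversion:
    def test_unit_coupling_is_plain_bp_per_turn(self):
        m = CouplingModel(coupling_efficiency=1.0)
        assert turns_rate_to_bp_rate(15.05, m) == 15.05 * 10.5

    def test_printed_conversion_chain(self):
        # 15.05 turns/s -> 158.0 bp/s at coupling 1, 210.7 (prints 211) at 0.75
        base = turns_rate_to_bp_rate(15.05, CouplingModel())
        assert base == pytest.approx(158.0, abs=0.05)
        at_075 = turns_rate_to_bp_rate(
            15.05, CouplingModel(coupling_efficiency=0.75))
        assert round(at_075) == 211
        at_05 = turns_rate_to_bp_rate(
            15.05, CouplingModel(coupling_efficiency=0.5))
        assert at_05 == pytest.approx(316.05, abs=0.01)

    def test_invalid_coupling_rejected(self):
        with pytest.raises(ValueError):
            CouplingModel(coupling_efficiency=0.0)
        with pytest.raises(ValueError):
            CouplingModel(coupling_efficiency=1.5)


class TestHatCurve:
    def test_apex_value(self):
        m = HatCurveModel()
        assert hat_extension(m, m.apex_turn) == m.apex_extension

    def test_clamped_at_zero_far_on_arm(self):
        m = HatCurveModel()
        assert hat_extension(m, 1e4) == 0.0

    def test_symmetry_with_equal_slopes(self):
        m = HatCurveModel(buckling_turn_pos=15, buckling_turn_neg=-15,
                          slope_pos=-0.05, slope_neg=0.05)
        for k in (20, 30, 55):
            assert hat_extension(m, m.apex_turn + k) == pytest.approx(
                hat_extension(m, m.apex_turn - k))

    def test_maximum_at_apex_on_grid(self):
        m = HatCurveModel()
        turns = np.linspace(-70, 70, 281)
        ext = hat_extension(m, turns)
        assert ext.max() == hat_extension(m, m.apex_turn)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            HatCurveModel(buckling_turn_neg=5, buckling_turn_pos=3)
        with pytest.raises(ValueError):
            HatCurveModel(slope_pos=0.1)
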