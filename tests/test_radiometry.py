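"""Unit and property tests for the raw-signal-to-temperature chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irproc import fixtures
from irproc.radiometry import (
    AcquisitionParams,
    RadiometryError,
    RawFrame,
    air_water_content,
    atmospheric_transmissivity,
    celsius_to_kelvin,
    component_signal,
    derive_atmosphere,
    frame_to_temperature,
    object_signal,
    object_temperature,
)

from .conftest import ATM, CAL, PARAMS, make_scene


class TestCelsiusToKelvin:
    @pytest.mark.parametrize("t_C, t_K", [(0.0, 273.15), (25.0, 298.15), (-70.0, 203.15)])
    def test_offset(self, t_C, t_K):
        assert celsius_to_kelvin(t_C) == pytest.approx(t_K, abs=1e-12)

    @pytest.mark.parametrize("t_C", [-273.15, -300.0])
    def test_absolute_zero_rejected(self, t_C):
        with pytest.raises(RadiometryError):
            celsius_to_kelvin(t_C)


class TestAirWaterContent:
    # frozen by direct evaluation of the cubic-exponential polynomial
    @pytest.mark.parametrize(
        "t, rh, expected",
        [
            (20.0, 0.5, 8.563981576394681),
            (30.0, 1.0, 30.22105448955349),
            (35.0, 0.0, 0.0),
        ],
    )
    def test_polynomial(self, t, rh, expected):
        assert air_water_content(t, rh) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("rh", [-0.1, 1.5, 50.0])
    def test_humidity_must_be_fraction(self, rh):
        with pytest.raises(RadiometryError):
            air_water_content(20.0, rh)


class TestTransmissivity:
    def test_zero_distance_is_unity(self):
        for H in (0.0, 8.56, 30.0):
            assert atmospheric_transmissivity(0.0, H, ATM) == 1.0

    def test_fixture_value(self):
        # frozen by direct evaluation of the two-term attenuation model
        H = air_water_content(20.0, 0.5)
        tau = atmospheric_transmissivity(4.0, H, ATM)
        assert tau == pytest.approx(0.9878431518903756, rel=1e-12)
        assert 0.0 < tau < 1.0

    def test_monotone_decreasing_in_distance_and_humidity(self):
        H = air_water_content(20.0, 0.5)
        taus_d = [atmospheric_transmissivity(d, H, ATM) for d in (0.0, 1.0, 4.0, 10.0, 50.0)]
        assert all(a > b for a, b in zip(taus_d, taus_d[1:]))
        taus_h = [
            atmospheric_transmissivity(10.0, air_water_content(20.0, rh), ATM)
            for rh in (0.1, 0.3, 0.5, 0.8, 1.0)
        ]
        assert all(a > b for a, b in zip(taus_h, taus_h[1:]))

    def test_clamped_to_unit_interval(self, caplog):
        # with these coefficients the beta terms are negative, so an extreme
        # water content over distance can push the raw expression above 1
        tau = atmospheric_transmissivity(10000.0, 10000.0, ATM)
        assert 0.0 < tau <= 1.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(RadiometryError):
            atmospheric_transmissivity(-1.0, 5.0, ATM)
        with pytest.raises(RadiometryError):
            atmospheric_transmissivity(1.0, -5.0, ATM)


class TestComponentSignal:
    def test_zero_weight_gives_offset(self):
        assert component_signal(300.0, 0.0, CAL) == CAL.O

    def test_fixture_value(self):
        # frozen by direct evaluation with the fixture constants
        assert component_signal(300.0, 0.95, CAL) == pytest.approx(3545.3993246043938, rel=1e-12)

    def test_signal_increases_without_bound(self):
        # denominator exp(B/T) - F -> 0+ as T grows (F = 1)
        s1 = component_signal(300.0, 0.9, CAL)
        s2 = component_signal(3000.0, 0.9, CAL)
        s3 = component_signal(300000.0, 0.9, CAL)
        assert s1 < s2 < s3
        assert s3 > 1e7

    def test_offset_free_variant(self):
        full = component_signal(300.0, 0.5, CAL, include_offset=True)
        bare = component_signal(300.0, 0.5, CAL, include_offset=False)
        assert full == pytest.approx(bare + CAL.O)

    def test_invalid_inputs(self):
        with pytest.raises(RadiometryError):
            component_signal(-5.0, 0.5, CAL)
        with pytest.raises(RadiometryError):
            component_signal(300.0, 1.5, CAL)


class TestObjectSignal:
    def test_identity_when_transparent(self):
        assert object_signal(12345.0, 1.0, 0.0, 0.0) == 12345.0

    def test_inverts_three_source_composition(self):
        a, b, c, tau = 9000.0, -6700.0, -7100.0, 0.97
        S = tau * a + tau * b + c
        assert object_signal(S, tau, b, c) == pytest.approx(a, rel=1e-12)

    def test_hand_arithmetic(self):
        assert object_signal(15000.0, 0.95, 14000.0, 13000.0) == pytest.approx(
            -11894.736842105263, rel=1e-12
        )

    def test_tau_must_be_positive(self):
        with pytest.raises(RadiometryError):
            object_signal(15000.0, 0.0, 0.0, 0.0)


class TestObjectTemperature:
    def test_inverse_of_component_signal(self):
        for T in np.linspace(233.15, 373.15, 29):
            for eps in (0.5, 0.95, 1.0):
                S = component_signal(float(T), eps, CAL)
                assert object_temperature(S, eps, CAL) == pytest.approx(T, abs=1e-9)

    def test_closed_form_at_unit_log(self):
        # log argument forced to e => temperature exactly B
        eps = 0.85
        S = CAL.O + CAL.G * eps / (CAL.R * (math.e - CAL.F))
        assert object_temperature(S, eps, CAL) == pytest.approx(CAL.B, rel=1e-12)

    def test_signal_at_offset_is_undefined(self):
        with pytest.raises(RadiometryError):
            object_temperature(CAL.O, 0.95, CAL)

    def test_strictly_increasing_in_signal(self):
        sigs = CAL.O + np.geomspace(10.0, 1e6, 25)
        temps = [object_temperature(float(s), 0.95, CAL) for s in sigs]
        assert all(a < b for a, b in zip(temps, temps[1:]))


class TestFrameToTemperature:
    def test_uniform_frame_round_trip(self):
        spec = make_scene(background_C=26.85)  # 300 K
        raw = fixtures.render_scene(spec)
        out = frame_to_temperature(raw, spec.params, spec.cal, spec.atm)
        assert np.all(np.isfinite(out.temp_C))
        assert np.abs(out.temp_C - 26.85).max() < 0.05

    def test_two_region_recovery_under_quantization(self, two_region_spec):
        truth, emis = fixtures.generate_scene(two_region_spec)
        raw = fixtures.forward_signal(truth, emis, two_region_spec)
        out = frame_to_temperature(
            raw, two_region_spec.params, two_region_spec.cal, two_region_spec.atm
        )
        hot = truth.temp_C == 40.0
        assert out.temp_C[hot].mean() == pytest.approx(40.0, abs=0.05)
        assert out.temp_C[~hot].mean() == pytest.approx(20.0, abs=0.05)

    def test_bad_pixel_becomes_nan_not_error(self):
        spec = make_scene()
        raw = fixtures.render_scene(spec)
        dn = raw.dn.copy()
        dn[3, 4] = 0  # object signal falls below the sensor offset
        out = frame_to_temperature(RawFrame(dn=dn), spec.params, spec.cal, spec.atm)
        assert np.isnan(out.temp_C[3, 4])
        mask = np.ones_like(dn, dtype=bool)
        mask[3, 4] = False
        assert np.all(np.isfinite(out.temp_C[mask]))

    def test_preserves_dn_ordering(self):
        spec = make_scene()
        dn = np.linspace(25000, 45000, 48 * 32).reshape(32, 48).astype(np.uint16)
        out = frame_to_temperature(RawFrame(dn=dn), spec.params, spec.cal, spec.atm)
        flat = out.temp_C.ravel()
        assert np.all(np.diff(flat) > 0)

    def test_higher_assumed_emissivity_lowers_temperature(self):
        spec = make_scene(background_C=35.0)
        raw = fixtures.render_scene(spec)
        temps = []
        for eps in (0.80, 0.90, 0.95, 1.0):
            p = AcquisitionParams(
                emissivity=eps,
                air_temp_C=spec.params.air_temp_C,
                rel_humidity=spec.params.rel_humidity,
                app_refl_temp_C=spec.params.app_refl_temp_C,
                distance_m=spec.params.distance_m,
            )
            temps.append(frame_to_temperature(raw, p, spec.cal, spec.atm).temp_C.mean())
        assert all(a > b for a, b in zip(temps, temps[1:]))

    def test_no_cold_floor_at_minus_70(self):
        spec = make_scene(background_C=-70.0)
        raw = fixtures.render_scene(spec)
        out = frame_to_temperature(raw, spec.params, spec.cal, spec.atm)
        assert np.abs(out.temp_C - (-70.0)).max() < 0.05


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    t_obj=st.floats(-70.0, 120.0),
    eps=st.floats(0.3, 1.0),
    t_air=st.floats(-10.0, 45.0),
    rh=st.floats(0.0, 1.0),
    d=st.floats(0.0, 100.0),
)
def test_round_trip_exactness_property(t_obj, eps, t_air, rh, d):
    """Composing the three-source signal and inverting recovers the object
    temperature to < 1e-6 degC without quantization, for any parameters."""
    cal = fixtures.DEFAULT_CAL
    params = AcquisitionParams(
        emissivity=eps, air_temp_C=t_air, rel_humidity=rh, app_refl_temp_C=t_air, distance_m=d
    )
    der = derive_atmosphere(params, cal, ATM)
    s_obj_true = component_signal(celsius_to_kelvin(t_obj), eps, cal)
    S = der.tau * s_obj_true + der.tau * der.S_refl + der.S_atm
    s_obj = object_signal(S, der.tau, der.S_refl, der.S_atm)
    T = object_temperature(float(s_obj), eps, cal) - 273.15
    assert T == pytest.approx(t_obj, abs=1e-6)
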