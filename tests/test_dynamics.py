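"""Drag profile, nondimensionalization, speed law and the inertial validation ODE."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from breakaway import (
    ConfigurationError,
    DragProfile,
    OffsetConvention,
    PhysicalParameters,
    energy_of_profile,
    integrate_inertial,
    nondimensionalize,
    quasi_steady_speed,
)

MEAN_CD = 0.9 / 1.43


class TestDragProfile:
    @pytest.mark.parametrize(
        "depth, expected",
        [
            (0.0, 0.9),                                   # front rider bears full drag
            (-3.0, 0.9),                                  # ahead of the peloton: solo drag
            (5.0, 0.05 + 0.85 * math.exp(-1.25)),         # five spacings deep
            (1e6, 0.05),                                  # deep-pack limit
        ],
    )
    def test_exponential_decay(self, depth, expected):
        profile = DragProfile()
        assert profile.drag_coefficient(depth) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(min_value=-10, max_value=200, allow_nan=False))
    def test_bounds_and_monotonicity(self, depth):
        profile = DragProfile()
        cd = profile.drag_coefficient(depth)
        assert profile.cd_min <= cd <= profile.cd_max
        if depth >= 0:
            assert profile.drag_coefficient(depth + 0.5) <= cd

    def test_rescaled_front_rider_full_drag(self):
        profile = DragProfile(
            peloton_mean_cd=MEAN_CD,
            offset_convention=OffsetConvention.EXPONENT_I_MINUS_1,
        )
        assert profile.rescaled_drag(1) == pytest.approx(1.43, rel=1e-12)

    def test_rescaled_lurker_matches_canonical_value(self):
        # Published dimensionless pair: depth-i exponent gives Cd,5 ~ 0.46.
        profile = DragProfile(peloton_mean_cd=MEAN_CD)
        assert profile.rescaled_drag(5) == pytest.approx(0.46, rel=0.02)

    def test_self_normalization(self):
        base = DragProfile()
        for i in (1, 3, 7):
            profile = DragProfile(peloton_mean_cd=base.drag_coefficient(float(i)))
            assert profile.rescaled_drag(i) == pytest.approx(1.0, rel=1e-12)

    def test_row_layout_mean_within_bounds(self):
        profile = DragProfile.from_row_layout(15, 5)
        assert profile.cd_min <= profile.peloton_mean_cd <= profile.cd_max
        # Single row: everyone at the front.
        assert DragProfile.from_row_layout(1, 75).peloton_mean_cd == pytest.approx(0.9)

    def test_missing_mean_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            DragProfile().rescaled_drag(5)

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ConfigurationError):
            DragProfile(cd_min=0.9, cd_max=0.05)
        with pytest.raises(ConfigurationError):
            DragProfile(decay=-1.0)


class TestNondimensionalization:
    def test_axle_spacing_ratio(self):
        phys = PhysicalParameters(axle_spacing=4.0, course_length=100_000.0)
        scales = nondimensionalize(phys, DragProfile(peloton_mean_cd=MEAN_CD))
        assert scales.delta == pytest.approx(4e-5, rel=1e-12)

    def test_inertia_parameter_from_stated_values(self):
        # <Cd>A = 0.4 m^2, <m> = 70 kg, rho = 1.225, L = 100 km -> 140/49000.
        phys = PhysicalParameters(mean_mass=70.0, air_density=1.225,
                                  frontal_area=0.5, course_length=1e5)
        scales = nondimensionalize(phys, DragProfile(peloton_mean_cd=0.8))
        assert scales.epsilon == pytest.approx(140.0 / 49000.0, rel=1e-12)

    def test_time_scale_homogeneity(self):
        # time_scale = (<Cd> rho A L^3 / 2P)^(1/3) is linear in L and scales
        # as the cube root of the drag-area and inverse power.
        profile = DragProfile(peloton_mean_cd=MEAN_CD)
        base = nondimensionalize(PhysicalParameters(course_length=1e4), profile)
        longer = nondimensionalize(PhysicalParameters(course_length=8e4), profile)
        assert longer.time_scale / base.time_scale == pytest.approx(8.0, rel=1e-12)
        stronger = nondimensionalize(
            PhysicalParameters(course_length=1e4, mean_initial_power=8 * 150.0), profile
        )
        assert stronger.time_scale / base.time_scale == pytest.approx(0.5, rel=1e-12)

    def test_unit_system_invariance(self):
        """Seconds out must not depend on whether inputs are SI or cgs."""
        si = PhysicalParameters()
        cgs = PhysicalParameters(
            rider_mass=si.rider_mass * 1e3,
            mean_mass=si.mean_mass * 1e3,
            air_density=si.air_density * 1e-3,       # g cm^-3
            frontal_area=si.frontal_area * 1e4,      # cm^2
            course_length=si.course_length * 1e2,    # cm
            axle_spacing=si.axle_spacing * 1e2,
            mean_initial_power=si.mean_initial_power * 1e7,  # erg/s
        )
        profile = DragProfile(peloton_mean_cd=MEAN_CD)
        t_si = nondimensionalize(si, profile).time_scale
        t_cgs = nondimensionalize(cgs, profile).time_scale
        assert t_cgs == pytest.approx(t_si, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            PhysicalParameters(air_density=-1.0)
        with pytest.raises(ConfigurationError):
            PhysicalParameters(axle_spacing=5_000.0)  # d not << L


class TestQuasiSteadySpeed:
    @pytest.mark.parametrize(
        "power, cd, expected",
        [(1.43, 1.43, 1.0), (1.0, 1.0, 1.0), (2.0, 1.43, (2.0 / 1.43) ** (1 / 3))],
    )
    def test_examples(self, power, cd, expected):
        assert quasi_steady_speed(power, cd) == pytest.approx(expected, rel=1e-12)

    @given(
        st.floats(min_value=0.05, max_value=20.0),
        st.floats(min_value=0.05, max_value=5.0),
    )
    def test_power_balance_residual(self, power, cd):
        v = quasi_steady_speed(power, cd)
        assert abs(power / v - cd * v * v) < 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            quasi_steady_speed(-1.0, 1.0)
        with pytest.raises(ValueError):
            quasi_steady_speed(1.0, 0.0)


class TestInertialIntegrator:
    def test_equilibrium_is_preserved(self):
        tf = integrate_inertial(lambda t: 1.0, 1.0, epsilon=0.005, x_target=1.0, v0=1.0)
        assert tf == pytest.approx(1.0, abs=1e-8)

    def test_quasi_steady_limit_from_off_equilibrium_start(self):
        tf = integrate_inertial(lambda t: 1.43, 1.43, epsilon=1e-4, x_target=1.0, v0=0.5)
        assert tf == pytest.approx(1.0, abs=5e-4)

    def test_error_decays_with_inertia_for_step_power(self):
        """Finish-time error vs the quasi-steady solution shrinks as eps -> 0."""
        cd = 1.43

        def profile(t: float) -> float:
            return 1.0 if t < 0.5 else 2.0

        v1 = quasi_steady_speed(1.0, cd)
        v2 = quasi_steady_speed(2.0, cd)
        x_half = v1 * 0.5
        tf_qs = 0.5 + (1.0 - x_half) / v2
        errors = []
        for eps in (0.02, 0.01, 0.005):
            tf = integrate_inertial(profile, cd, epsilon=eps, x_target=1.0, v0=v1)
            errors.append(abs(tf - tf_qs))
        assert errors[0] > errors[1] > errors[2]
        # Roughly linear decay: halving eps roughly halves the error.
        assert errors[0] / errors[2] == pytest.approx(4.0, rel=0.5)


class TestEnergyOfProfile:
    def test_unit_power_unit_race(self):
        assert energy_of_profile(lambda t: 1.0, 1.0) == pytest.approx(1.0, rel=1e-10)

    def test_zero_power(self):
        assert energy_of_profile(lambda t: 0.0, 3.0) == pytest.approx(0.0, abs=1e-12)

    def test_decaying_burst_against_antiderivative(self):
        # (Pmax-Ps)e^{-mu t} + Ps from 0 to 1: Ps + (Pmax-Ps)(1-e^-mu)/mu.
        pmax, ps, mu = 2.0, 0.46, 1.0
        expected = ps + (pmax - ps) * (1.0 - math.exp(-mu)) / mu
        got = energy_of_profile(lambda t: (pmax - ps) * math.exp(-mu * t) + ps, 1.0)
        assert got == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(1.4334656605959788, rel=1e-12)

    def test_negative_horizon_rejected(self):
        with pytest.raises(ValueError):
            energy_of_profile(lambda t: 1.0, -0.1)
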