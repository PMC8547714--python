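"""Closed-form forward models: Poiseuille flow, relaxation spectra, vaso scaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from mcflow import (
    ChannelSpec,
    FlowConditions,
    Fluid,
    RelaxationSpectrum,
    TissueBlock,
    VasoScale,
    bounded_relaxation_stress,
    channel_time_constant,
    chi_from_pressure_ratio,
    dynamic_from_kinematic,
    kinematic_from_efflux,
    poiseuille_pressure_drop,
    step_relaxation_stress,
    transform_spectrum,
    unbounded_powerlaw_stress,
    vaso_stress_scale,
)


def spectral_quadrature(amplitude, b, t, t_min=0.0, t_max=np.inf):
    """Independent oracle: direct integration of the exponential-decay
    kernel A0 * tau**(-b) * exp(-t/tau) over the time-constant spectrum."""
    value, _ = integrate.quad(
        lambda tau: amplitude * tau**-b * np.exp(-t / tau), t_min, t_max, limit=500
    )
    return value


class TestPoiseuille:
    def test_zero_flow_zero_drop(self, castor, channel):
        assert poiseuille_pressure_drop(castor, channel, FlowConditions(0.0)) == 0.0

    def test_fourth_power_radius_scaling(self, castor, channel):
        flow = FlowConditions(volume_rate=1e-9)
        wide = ChannelSpec(radius=2 * channel.radius, length=channel.length)
        dp = poiseuille_pressure_drop(castor, channel, flow)
        assert poiseuille_pressure_drop(castor, wide, flow) == pytest.approx(dp / 16)

    def test_hand_evaluated_value(self, castor, channel):
        # 8 * 0.98 * 0.032 * 1e-9 / (pi * 0.0015**4), evaluated independently
        dp = poiseuille_pressure_drop(castor, channel, FlowConditions(1e-9))
        assert dp == pytest.approx(15.774337628797907, rel=1e-12)

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError, match="radius"):
            ChannelSpec(radius=0.0, length=0.032)


class TestChannelTimeConstant:
    def test_printed_castor_oil_value(self, castor, channel, block):
        # eta * A0' * x0 / (C r^4 E) with the phantom geometry: ~104.5 s
        tau = channel_time_constant(castor, channel, block)
        assert tau == pytest.approx(104.5, rel=0.01)

    def test_linear_in_viscosity(self, castor, channel, block):
        doubled = Fluid(2 * castor.dynamic_viscosity, castor.density)
        assert channel_time_constant(doubled, channel, block) == pytest.approx(
            2 * channel_time_constant(castor, channel, block)
        )

    def test_viscosity_ratio_carries_to_tau(self, castor, olive, channel, block):
        # olive oil tau is the castor tau divided by 0.98/0.08 = 12.25
        ratio = channel_time_constant(castor, channel, block) / channel_time_constant(
            olive, channel, block
        )
        assert ratio == pytest.approx(12.25, rel=1e-12)

    @pytest.mark.parametrize(
        "factor_fn, expect_increase",
        [
            (lambda c, ch, b: (Fluid(2 * c.dynamic_viscosity, c.density), ch, b), True),
            (lambda c, ch, b: (c, ch, TissueBlock(2 * b.cross_section_area, b.x0, b.youngs_modulus)), True),
            (lambda c, ch, b: (c, ch, TissueBlock(b.cross_section_area, 2 * b.x0, b.youngs_modulus)), True),
            (lambda c, ch, b: (c, ch, TissueBlock(b.cross_section_area, b.x0, 2 * b.youngs_modulus)), False),
            (lambda c, ch, b: (c, ChannelSpec(2 * ch.radius, ch.length), b), False),
            (lambda c, ch, b: (c, ChannelSpec(ch.radius, 2 * ch.length), b), True),
        ],
        ids=["eta", "area", "x0", "modulus", "radius", "length"],
    )
    def test_monotonicity(self, castor, channel, block, factor_fn, expect_increase):
        base = channel_time_constant(castor, channel, block)
        changed = channel_time_constant(*factor_fn(castor, channel, block))
        assert (changed > base) == expect_increase

    def test_channel_length_acts_through_geometric_constant(self, channel):
        # doubling L halves C = C1*pi/(8L)
        longer = ChannelSpec(channel.radius, 2 * channel.length)
        assert longer.geometric_constant == pytest.approx(
            channel.geometric_constant / 2
        )


class TestStepRelaxation:
    def test_initial_value_and_time_constant(self, block):
        assert step_relaxation_stress(block, 0.05, 104.5, 0.0) == pytest.approx(
            0.05 * 7000
        )
        assert step_relaxation_stress(block, 0.05, 104.5, 104.5) == pytest.approx(
            0.05 * 7000 / math.e
        )

    def test_hand_evaluated_value(self, block):
        # 0.05 * 7000 * exp(-100 / 104.5), evaluated independently
        assert step_relaxation_stress(block, 0.05, 104.5, 100.0) == pytest.approx(
            134.42351229243275, rel=1e-12
        )

    def test_rejects_negative_time(self, block):
        with pytest.raises(ValueError, match="negative"):
            step_relaxation_stress(block, 0.05, 104.5, -1.0)


class TestPowerLawSpectra:
    def test_known_gamma_value(self):
        assert unbounded_powerlaw_stress(1.0, 1.5, 1.0) == pytest.approx(
            math.sqrt(math.pi)
        )

    def test_strictly_decreasing(self):
        t = np.logspace(-1, 3, 50)
        sigma = unbounded_powerlaw_stress(3.0, 1.4, t)
        assert np.all(np.diff(sigma) < 0)

    @pytest.mark.parametrize("t", [0.5, 1.0, 5.0, 50.0])
    def test_unbounded_matches_quadrature(self, t):
        closed = unbounded_powerlaw_stress(2.0, 1.3, t)
        assert closed == pytest.approx(spectral_quadrature(2.0, 1.3, t), rel=1e-6)

    @pytest.mark.parametrize("t", [1.0, 10.0, 100.0])
    def test_bounded_matches_quadrature(self, t):
        spectrum = RelaxationSpectrum(amplitude=1.0, b=1.5, t_min=0.5, t_max=50.0)
        closed = bounded_relaxation_stress(spectrum, t)
        oracle = spectral_quadrature(1.0, 1.5, t, 0.5, 50.0)
        assert closed == pytest.approx(oracle, rel=1e-6)

    @pytest.mark.parametrize("b", [1.1, 1.3, 1.5, 1.7, 1.9])
    def test_bounded_quadrature_grid(self, b):
        for t in np.logspace(-1, 3, 20):
            spectrum = RelaxationSpectrum(1.0, b, t_min=0.05, t_max=500.0)
            closed = bounded_relaxation_stress(spectrum, t)
            oracle = spectral_quadrature(1.0, b, t, 0.05, 500.0)
            assert closed == pytest.approx(oracle, rel=1e-6)

    def test_unbounded_is_wide_bound_limit(self):
        # truncating the spectrum 6 decades beyond t leaves a relative
        # tail error of 2/sqrt(pi)*1e-3 for b = 1.5 (upper-tail integral
        # of tau**-1.5), so agreement is asserted at twice that
        for t in [0.5, 2.0, 20.0]:
            spectrum = RelaxationSpectrum(1.0, 1.5, t_min=1e-6 * t, t_max=1e6 * t)
            assert bounded_relaxation_stress(spectrum, t) == pytest.approx(
                unbounded_powerlaw_stress(1.0, 1.5, t), rel=2e-3
            )

    def test_degenerate_interval_vanishes(self):
        spectrum = RelaxationSpectrum(1.0, 1.5, t_min=5.0, t_max=5.0 * (1 + 1e-12))
        assert bounded_relaxation_stress(spectrum, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_t_and_amplitude(self):
        t = np.logspace(-1, 2, 30)
        low = bounded_relaxation_stress(RelaxationSpectrum(1.0, 1.4, 0.5, 50.0), t)
        high = bounded_relaxation_stress(RelaxationSpectrum(2.0, 1.4, 0.5, 50.0), t)
        assert np.all(np.diff(low) < 0)
        assert np.all(high > low)

    @pytest.mark.parametrize("bad_b", [0.5, 1.0, 2.0, 2.5])
    def test_exponent_domain_enforced(self, bad_b):
        with pytest.raises(ValueError, match="b"):
            unbounded_powerlaw_stress(1.0, bad_b, 1.0)
        with pytest.raises(ValueError):
            RelaxationSpectrum(1.0, bad_b, 0.5, 50.0)

    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError, match="Tmin"):
            RelaxationSpectrum(1.0, 1.5, t_min=50.0, t_max=0.5)

    def test_rejects_nonpositive_time(self):
        with pytest.raises(ValueError):
            bounded_relaxation_stress(RelaxationSpectrum(1.0, 1.5, 0.5, 50.0), 0.0)


class TestVasoTransformation:
    def test_identity_at_unit_chi(self):
        spectrum = RelaxationSpectrum(2.0, 1.5, 0.5, 50.0)
        out = transform_spectrum(spectrum, VasoScale(1.0))
        assert out == spectrum

    def test_chi_roundtrip_is_identity(self):
        spectrum = RelaxationSpectrum(2.0, 1.4, 0.5, 50.0)
        scale = VasoScale(0.8)
        back = transform_spectrum(transform_spectrum(spectrum, scale), scale.inverse())
        assert back.amplitude == pytest.approx(spectrum.amplitude)
        assert back.t_min == pytest.approx(spectrum.t_min)
        assert back.t_max == pytest.approx(spectrum.t_max)

    def test_constriction_raises_time_constants(self):
        # chi^4 = 40/90 exactly maps Tmax 10 s -> 22.5 s
        chi = (40.0 / 90.0) ** 0.25
        out = transform_spectrum(
            RelaxationSpectrum(1.0, 1.5, 1.0, 10.0), VasoScale(chi)
        )
        assert out.t_max == pytest.approx(10.0 * 90.0 / 40.0, rel=1e-12)
        assert out.t_min == pytest.approx(90.0 / 40.0, rel=1e-12)

    def test_transformed_stress_is_scaled_baseline(self):
        # stress of the transformed spectrum equals the baseline closed form
        # with mapped bounds, multiplied by chi**(-4*(b-1))
        spectrum = RelaxationSpectrum(1.3, 1.6, 0.4, 80.0)
        scale = VasoScale(0.85)
        mapped = transform_spectrum(spectrum, scale)
        t = np.logspace(-1, 2, 25)
        with_mapped_bounds = bounded_relaxation_stress(
            RelaxationSpectrum(spectrum.amplitude, spectrum.b, mapped.t_min, mapped.t_max), t
        )
        expected = vaso_stress_scale(scale, spectrum.b) * with_mapped_bounds
        np.testing.assert_allclose(
            bounded_relaxation_stress(mapped, t), expected, rtol=1e-12
        )

    def test_discussion_stress_scale(self):
        # chi = 0.817 and b = 1.5 give 1/chi^2, approximately 1.5
        assert vaso_stress_scale(VasoScale(0.817), 1.5) == pytest.approx(1.5, abs=0.01)
        assert vaso_stress_scale(VasoScale(0.817), 1.5) == pytest.approx(
            1 / 0.817**2, rel=1e-12
        )

    @pytest.mark.parametrize("b", [1.1, 1.5, 1.9])
    def test_unit_chi_scale_is_one(self, b):
        assert vaso_stress_scale(VasoScale(1.0), b) == 1.0

    def test_scale_tends_to_one_as_b_to_one(self):
        assert vaso_stress_scale(VasoScale(0.5), 1.0 + 1e-12) == pytest.approx(1.0)

    def test_chi_from_placental_pressures(self):
        assert chi_from_pressure_ratio(40.0, 90.0).chi == pytest.approx(0.8165, abs=5e-5)

    @pytest.mark.parametrize(
        "dp1, dp2, expected", [(50.0, 50.0, 1.0), (10.0, 160.0, 0.5)]
    )
    def test_chi_special_ratios(self, dp1, dp2, expected):
        assert chi_from_pressure_ratio(dp1, dp2).chi == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(chi=st.floats(0.2, 5.0))
    def test_pressure_ratio_roundtrip(self, chi):
        # dp2/dp1 = chi^-4 inverts chi_from_pressure_ratio exactly
        dp1 = 40.0
        dp2 = dp1 * chi**-4
        assert chi_from_pressure_ratio(dp1, dp2).chi == pytest.approx(chi, rel=1e-9)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            chi_from_pressure_ratio(0.0, 90.0)
        with pytest.raises(ValueError):
            VasoScale(0.0)


class TestViscometry:
    def test_efflux_conversion(self):
        # 100 s x 0.4511 cSt/s = 45.11 cSt = 4.511e-5 m^2/s
        assert kinematic_from_efflux(100.0, 0.4511) == pytest.approx(4.511e-5)
        assert kinematic_from_efflux(0.0, 0.4511) == 0.0

    def test_unit_roundtrip(self):
        nu = kinematic_from_efflux(123.4, 0.4511)
        assert nu / 1e-6 == pytest.approx(123.4 * 0.4511, rel=1e-12)

    def test_dynamic_conversion(self):
        assert dynamic_from_kinematic(1e-4, 1000.0) == pytest.approx(0.1)
        assert dynamic_from_kinematic(0.0, 1000.0) == 0.0

    def test_oil_viscosity_ratio(self, castor, olive):
        assert castor.dynamic_viscosity / olive.dynamic_viscosity == pytest.approx(
            12.25
        )

    def test_fluid_consistency_check(self):
        Fluid(0.1, 1000.0, kinematic_viscosity=1e-4)  # consistent
        with pytest.raises(ValueError, match="inconsistent"):
            Fluid(0.1, 1000.0, kinematic_viscosity=2e-4)

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            kinematic_from_efflux(-1.0, 0.4511)
        with pytest.raises(ValueError):
            dynamic_from_kinematic(1e-4, 0.0)
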