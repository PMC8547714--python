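"""Physical parameter types and closed-form microchannel flow model (MCFM) forward models.

The MCFM attributes stress relaxation in soft, vascularized tissue to
Poiseuille outflow from fluid-filled channels embedded in an elastic
matrix.  Each channel of radius ``r`` and length ``L``, filled with a
fluid of dynamic viscosity ``eta``, behaves as a dashpot in series with
the elastic background and contributes a single exponential decay with
characteristic time constant

    tau = eta * A0' * x0 / (C * r**4 * E),        C = C1 * pi / (8 * L)

where ``A0'`` and ``x0`` are the cross-sectional area and height of the
tissue block and ``E`` its Young's modulus.  A fractal vasculature is
modelled as a continuous power-law spectrum of such time constants,
which integrates to a power-law stress relaxation (complete gamma
function) when the spectrum is unbounded, and to a difference of upper
incomplete gamma functions when the smallest and largest vessels impose
bounds ``Tmin`` and ``Tmax``.

Vasoconstriction multiplies every vessel radius by a scale factor
``chi < 1``; through the fourth-power radius dependence this divides
every time constant by ``chi**4`` and raises the relaxation stress by
``chi**(-4*(b-1))``.

All quantities are SI internally (m, s, Pa, Pa*s).  mmHg and cSt enter
only through the explicit converters at the bottom of this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "ChannelSpec",
    "TissueBlock",
    "Fluid",
    "FlowConditions",
    "RelaxationSpectrum",
    "VasoScale",
    "poiseuille_pressure_drop",
    "channel_time_constant",
    "step_relaxation_stress",
    "unbounded_powerlaw_stress",
    "bounded_relaxation_stress",
    "transform_spectrum",
    "vaso_stress_scale",
    "chi_from_pressure_ratio",
    "kinematic_from_efflux",
    "dynamic_from_kinematic",
    "upper_incomplete_gamma",
    "CST_TO_M2_PER_S",
]

#: 1 centistokes in m^2/s.
CST_TO_M2_PER_S = 1e-6


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelSpec:
    """A cylindrical fluid channel: radius, length and the Poiseuille
    proportionality constant ``C = C1 * pi / (8 * L)``.

    ``c1`` is the dimensionless constant relating the channel pressure
    drop to the applied normal stress (``dP ~= C1 * sigma_x``); the
    default ``c1 = 1`` reproduces the bare ``pi / (8 L)`` geometric
    constant.
    """

    radius: float
    length: float
    c1: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"channel radius must be > 0, got {self.radius}")
        if self.length <= 0:
            raise ValueError(f"channel length must be > 0, got {self.length}")
        if self.c1 <= 0:
            raise ValueError(f"C1 must be > 0, got {self.c1}")

    @property
    def geometric_constant(self) -> float:
        """``C = C1 * pi / (8 * L)`` in 1/m."""
        return self.c1 * math.pi / (8.0 * self.length)


@dataclass(frozen=True)
class TissueBlock:
    """Elastic block surrounding the channels: cross-section area (m^2),
    height along the compression axis (m) and Young's modulus (Pa)."""

    cross_section_area: float
    x0: float
    youngs_modulus: float

    def __post_init__(self) -> None:
        for name in ("cross_section_area", "x0", "youngs_modulus"):
            value = getattr(self, name)
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class Fluid:
    """Channel fluid: dynamic viscosity (Pa*s), density (kg/m^3) and an
    optional kinematic viscosity (m^2/s) that must satisfy
    ``eta = nu * rho`` when given."""

    dynamic_viscosity: float
    density: float
    kinematic_viscosity: float | None = None

    def __post_init__(self) -> None:
        if self.dynamic_viscosity <= 0:
            raise ValueError(
                f"dynamic_viscosity must be > 0, got {self.dynamic_viscosity}"
            )
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.kinematic_viscosity is not None:
            implied = self.kinematic_viscosity * self.density
            if not math.isclose(implied, self.dynamic_viscosity, rel_tol=1e-9):
                raise ValueError(
                    "inconsistent viscosities: eta != nu * rho "
                    f"({self.dynamic_viscosity} != {implied})"
                )


@dataclass(frozen=True)
class FlowConditions:
    """Volumetric flow rate (m^3/s) and pressure drop (Pa)."""

    volume_rate: float = 0.0
    pressure_drop: float = 0.0

    def __post_init__(self) -> None:
        if self.volume_rate < 0:
            raise ValueError(f"volume_rate must be >= 0, got {self.volume_rate}")
        if self.pressure_drop < 0:
            raise ValueError(f"pressure_drop must be >= 0, got {self.pressure_drop}")


@dataclass(frozen=True)
class RelaxationSpectrum:
    """Power-law relaxation spectrum ``A(tau) = A0 * tau**(-b)`` with
    time-constant bounds ``Tmin < tau < Tmax``.

    The working domain is ``1 < b < 2`` so that ``Gamma(b - 1)`` is
    finite and the spectral integrals converge at both ends.  The
    derived exponent ``a = b - 1`` appears in the incomplete-gamma
    closed form.
    """

    amplitude: float
    b: float
    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if not 1.0 < self.b < 2.0:
            raise ValueError(f"power-law exponent b must lie in (1, 2), got {self.b}")
        if not 0.0 < self.t_min < self.t_max:
            raise ValueError(
                f"need 0 < Tmin < Tmax, got Tmin={self.t_min}, Tmax={self.t_max}"
            )

    @property
    def a(self) -> float:
        """Derived exponent ``a = b - 1``."""
        return self.b - 1.0


@dataclass(frozen=True)
class VasoScale:
    """Multiplicative vessel-radius scale factor ``chi``: ``chi < 1`` is
    vasoconstriction, ``chi > 1`` vasodilation."""

    chi: float

    def __post_init__(self) -> None:
        if self.chi <= 0:
            raise ValueError(f"chi must be > 0, got {self.chi}")

    @property
    def is_constriction(self) -> bool:
        return self.chi < 1.0

    def inverse(self) -> "VasoScale":
        return VasoScale(1.0 / self.chi)


# ---------------------------------------------------------------------------
# Poiseuille flow and the channel time constant
# ---------------------------------------------------------------------------

def poiseuille_pressure_drop(
    fluid: Fluid, channel: ChannelSpec, flow: FlowConditions
) -> float:
    """Laminar-flow pressure drop ``dP = 8 * eta * L * Q / (pi * r**4)`` in Pa."""
    return (
        8.0
        * fluid.dynamic_viscosity
        * channel.length
        * flow.volume_rate
        / (math.pi * channel.radius**4)
    )


def channel_time_constant(
    fluid: Fluid, channel: ChannelSpec, block: TissueBlock
) -> float:
    """Characteristic relaxation time constant of one fluid-filled channel.

    ``tau = eta * A0' * x0 / (C * r**4 * E)`` (seconds): linear in fluid
    viscosity and block dimensions, inversely proportional to stiffness
    and to the fourth power of the channel radius — the lever through
    which both fluid swaps and vasoconstriction act.
    """
    return (
        fluid.dynamic_viscosity
        * block.cross_section_area
        * block.x0
        / (channel.geometric_constant * channel.radius**4 * block.youngs_modulus)
    )


def step_relaxation_stress(
    block: TissueBlock, strain0: float, tau: float, t
):
    """Single-channel step-strain relaxation ``sigma(t) = eps0 * E * exp(-t / tau)``.

    ``t`` may be a scalar or array of non-negative times (s).
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative times are not in the model's domain")
    out = strain0 * block.youngs_modulus * np.exp(-t / tau)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Power-law relaxation spectra
# ---------------------------------------------------------------------------

def upper_incomplete_gamma(a: float, x) :
    """Non-regularized upper incomplete gamma ``Gamma(a, x) = int_x^inf u**(a-1) e**(-u) du``.

    scipy exposes only the regularized form ``gammaincc``; multiply back
    by the complete ``Gamma(a)``.
    """
    return special.gammaincc(a, x) * special.gamma(a)


def unbounded_powerlaw_stress(amplitude: float, b: float, t):
    """Two-parameter relaxation ``sigma(t) = A0 * t**(1-b) * Gamma(b-1)``.

    This is the integral of the kernel ``A0 * tau**(-b) * exp(-t/tau)``
    over all time constants ``tau`` in (0, inf); it requires
    ``1 < b < 2`` and ``t > 0``.
    """
    if not 1.0 < b < 2.0:
        raise ValueError(f"power-law exponent b must lie in (1, 2), got {b}")
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("the power-law relaxation closed form requires t > 0")
    out = amplitude * t ** (1.0 - b) * special.gamma(b - 1.0)
    return out if out.ndim else float(out)


def bounded_relaxation_stress(spectrum: RelaxationSpectrum, t):
    """Four-parameter bounded-spectrum relaxation.

    ``sigma(t) = A0 * [Gamma(a, t/Tmax) - Gamma(a, t/Tmin)] / t**a`` with
    ``a = b - 1`` and ``Gamma(a, x)`` the non-regularized upper
    incomplete gamma function.  Equals the integral of
    ``A0 * tau**(-b) * exp(-t/tau)`` over ``Tmin < tau < Tmax`` and
    reduces to :func:`unbounded_powerlaw_stress` as ``Tmin -> 0`` and
    ``Tmax -> inf``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("the bounded relaxation closed form requires t > 0")
    a = spectrum.a
    out = (
        spectrum.amplitude
        * (
            upper_incomplete_gamma(a, t / spectrum.t_max)
            - upper_incomplete_gamma(a, t / spectrum.t_min)
        )
        / t**a
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Vasoconstriction / vasodilation transformations
# ---------------------------------------------------------------------------

def transform_spectrum(
    spectrum: RelaxationSpectrum, scale: VasoScale
) -> RelaxationSpectrum:
    """Relaxation spectrum after scaling every vessel radius by ``chi``.

    Because ``tau`` is proportional to ``r**(-4)``, every time constant
    maps as ``tau -> tau / chi**4`` (vasoconstriction, chi < 1, raises
    the time constants), and the spectrum amplitude maps as
    ``A0 -> A0 * chi**(-4*(b-1))`` so that the relaxation stress of the
    new state carries the prefactor ``chi**(-4*(b-1))``.  ``b`` is a
    property of the vasculature's branching geometry and is unchanged.
    """
    chi4 = scale.chi**4
    return RelaxationSpectrum(
        amplitude=spectrum.amplitude * scale.chi ** (-4.0 * (spectrum.b - 1.0)),
        b=spectrum.b,
        t_min=spectrum.t_min / chi4,
        t_max=spectrum.t_max / chi4,
    )


def vaso_stress_scale(scale: VasoScale, b: float) -> float:
    """Multiplicative change of the relaxation stress under radius scale ``chi``.

    ``chi**(-4*(b-1))``; for ``b = 1.5`` this is ``1/chi**2``, so a
    radius reduction to 81.7% of baseline predicts a ~1.5x elevation of
    the stress response.
    """
    if not 1.0 < b < 2.0:
        raise ValueError(f"power-law exponent b must lie in (1, 2), got {b}")
    return scale.chi ** (-4.0 * (b - 1.0))


def chi_from_pressure_ratio(dp1: float, dp2: float) -> VasoScale:
    """Radius scale factor implied by a perfusion-pressure change at constant flow.

    Poiseuille's law at fixed ``Q`` gives ``dP2 / dP1 = (r1 / r2)**4 = chi**(-4)``,
    hence ``chi = (dp1 / dp2)**(1/4)``.  Any consistent pressure unit
    (mmHg, Pa, ...) may be used.
    """
    if dp1 <= 0 or dp2 <= 0:
        raise ValueError(f"pressures must be > 0, got {dp1}, {dp2}")
    return VasoScale((dp1 / dp2) ** 0.25)


# ---------------------------------------------------------------------------
# Viscometry conversions
# ---------------------------------------------------------------------------

def kinematic_from_efflux(
    efflux_time: float, viscometer_constant_cst_per_s: float
) -> float:
    """Kinematic viscosity (m^2/s) from a capillary-viscometer efflux time.

    The viscometer constant is in cSt/s as supplied by manufacturers;
    the product ``time * constant`` (cSt) is converted to SI.
    """
    if efflux_time < 0:
        raise ValueError(f"efflux time must be >= 0, got {efflux_time}")
    return efflux_time * viscometer_constant_cst_per_s * CST_TO_M2_PER_S


def dynamic_from_kinematic(nu: float, rho: float) -> float:
    """Dynamic viscosity ``eta = nu * rho`` (Pa*s)."""
    if nu < 0:
        raise ValueError(f"kinematic viscosity must be >= 0, got {nu}")
    if rho <= 0:
        raise ValueError(f"density must be > 0, got {rho}")
    return nu * rho
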