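"""Stress responses to ramp-plus-hold strain programs and the two-fluid difference model.

An ideal step strain cannot be applied by a test machine; the practical
program ramps linearly to the target strain ``eps0`` over ``T0`` seconds
and then holds.  For a linear material the ramp response is the running
integral of the ideal step response, and the ramp-plus-hold response is
the superposition of a ramp-up and a delayed, negated ramp-down.

For a channel whose ideal step response is ``B0 * exp(-t / tau)``:

    ramp:       sigma(t) = B0 * tau * (1 - exp(-t / tau))
    ramp+hold:  sigma(t) = ramp(t) - ramp(t - T0) * H(t - T0)

Differencing two otherwise identical samples whose channels carry
fluids of different viscosity cancels the purely elastic background and
isolates the two fluid terms; an additive constant ``delta`` absorbs
small sample-to-sample offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StrainProgram",
    "RampHoldParams",
    "TwoFluidDifferenceParams",
    "ramp_stress",
    "ramp_plus_hold_stress",
    "two_fluid_stress_difference",
]


@dataclass(frozen=True)
class StrainProgram:
    """Ramp-plus-hold strain program: target strain ``eps0``, ramp
    duration ``T0`` (s) and total program duration (s)."""

    strain0: float
    ramp_duration: float
    total_duration: float

    def __post_init__(self) -> None:
        if not 0.0 < self.strain0 < 1.0:
            raise ValueError(f"strain0 must lie in (0, 1), got {self.strain0}")
        if not 0.0 < self.ramp_duration < self.total_duration:
            raise ValueError(
                "need 0 < ramp_duration < total_duration, got "
                f"{self.ramp_duration}, {self.total_duration}"
            )

    @property
    def ramp_slope(self) -> float:
        """Strain rate during the ramp, ``eps0 / T0`` (1/s)."""
        return self.strain0 / self.ramp_duration

    def strain(self, t):
        """Strain at time(s) ``t``: linear up to ``T0``, constant after."""
        t = np.asarray(t, dtype=float)
        out = self.strain0 * np.clip(t / self.ramp_duration, 0.0, 1.0)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class RampHoldParams:
    """Single-channel response parameters: step amplitude ``B0`` (Pa/s)
    and fluid time constant ``tau`` (s).

    ``B0`` carries Pa/s and absorbs the modulus, the ramp slope and any
    channel-count factor; no attempt is made to decompose it.
    """

    amplitude: float
    tau: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class TwoFluidDifferenceParams:
    """The five parameters of the two-fluid stress-difference model plus
    the (measured, not fitted) ramp duration.

    Canonical ordering is ``tau2 >= tau1``: component 2 is the more
    viscous fluid with the slower decay.
    """

    b1: float
    tau1: float
    b2: float
    tau2: float
    delta: float
    ramp_duration: float

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError(
                f"time constants must be > 0, got tau1={self.tau1}, tau2={self.tau2}"
            )
        if self.tau2 < self.tau1:
            raise ValueError(
                "canonical ordering requires tau2 >= tau1, got "
                f"tau1={self.tau1}, tau2={self.tau2}"
            )
        if self.ramp_duration <= 0:
            raise ValueError(f"ramp_duration must be > 0, got {self.ramp_duration}")


def ramp_stress(params: RampHoldParams, t):
    """Stress response to a ramp strain: ``B0 * tau * (1 - exp(-t / tau))``.

    Rises from 0 and saturates at the plateau ``B0 * tau``; equal to the
    running integral of the ideal step response ``B0 * exp(-t / tau)``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative times are not in the model's domain")
    out = params.amplitude * params.tau * (1.0 - np.exp(-t / params.tau))
    return out if out.ndim else float(out)


def ramp_plus_hold_stress(params: RampHoldParams, ramp_duration: float, t):
    """Stress response to a ramp of duration ``T0`` followed by a hold.

    ``ramp(t) - ramp(t - T0) * H(t - T0)`` with the Heaviside convention
    ``H(0) = 1`` (immaterial to values since ``ramp(0) = 0``).  The
    response is continuous, peaks at ``t = T0`` and decays to zero as
    the fluid contribution relaxes.
    """
    if ramp_duration <= 0:
        raise ValueError(f"ramp_duration must be > 0, got {ramp_duration}")
    t = np.asarray(t, dtype=float)
    up = ramp_stress(params, t)
    shifted = np.clip(t - ramp_duration, 0.0, None)
    down = ramp_stress(params, shifted) * (t >= ramp_duration)
    out = up - down
    return out if out.ndim else float(out)


def two_fluid_stress_difference(params: TwoFluidDifferenceParams, t):
    """Difference of two ramp-plus-hold responses plus an offset.

    ``delta_sigma(t) = rph(B2, tau2, t) - rph(B1, tau1, t) + delta``;
    tends to ``delta`` as both fluid terms relax.
    """
    high = ramp_plus_hold_stress(
        RampHoldParams(params.b2, params.tau2), params.ramp_duration, t
    )
    low = ramp_plus_hold_stress(
        RampHoldParams(params.b1, params.tau1), params.ramp_duration, t
    )
    return high - low + params.delta
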