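"""Seeded generators for virtual phantom and wave experiments.

No raw data accompany the physical experiments this package models, so
every analysis stage is exercised on synthetic inputs generated here:

* virtual ramp-plus-hold compression of a gelatin block with six
  fluid-filled channels (a channel-in-phantom, CIP, experiment),
  producing stress-relaxation traces and paired-sample differences;
* virtual two-location shear-wave tracking with a prescribed
  power-law dispersion ``c(f) = c' * f**a'``, producing waveform pairs
  and noisy dispersion curves.

All generators are pure functions of their configuration and seed:
the same seed reproduces the output bitwise, different seeds differ
only in the noise realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .core import ChannelSpec, Fluid, TissueBlock, channel_time_constant
from .dispersion import DispersionCurve, WaveformPair
from .fitting import StressTrace
from .ramp_hold import RampHoldParams, StrainProgram, ramp_plus_hold_stress

__all__ = [
    "PhantomExperimentConfig",
    "WaveSynthConfig",
    "default_block",
    "default_channels",
    "castor_oil",
    "olive_oil",
    "BASELINE_DISPERSION",
    "VASOCONSTRICTION_DISPERSION",
    "simulate_relaxation_trace",
    "simulate_paired_difference",
    "simulate_wave_pair",
    "simulate_dispersion_measurements",
]

#: (c' in m/s*Hz^-a', a') for the baseline perfusion state.
BASELINE_DISPERSION = (0.412, 0.242)
#: (c', a') for the vasoconstricted state.
VASOCONSTRICTION_DISPERSION = (0.589, 0.257)


def default_block() -> TissueBlock:
    """35 mm x 35 mm x 38 mm gelatin block, E = 7 kPa."""
    return TissueBlock(cross_section_area=0.035**2, x0=0.038, youngs_modulus=7000.0)


def default_channels(count: int = 6) -> tuple[ChannelSpec, ...]:
    """``count`` identical channels, 3 mm diameter, 32 mm long."""
    return tuple(ChannelSpec(radius=0.0015, length=0.032) for _ in range(count))


def castor_oil() -> Fluid:
    return Fluid(dynamic_viscosity=0.98, density=961.0)


def olive_oil() -> Fluid:
    return Fluid(dynamic_viscosity=0.08, density=911.0)


@dataclass(frozen=True)
class PhantomExperimentConfig:
    """A virtual stress-relaxation compression test on a channel-bearing block.

    The crosshead moves at ``crosshead_speed`` until the target strain
    ``strain0`` is reached, giving a ramp duration
    ``T0 = strain0 * x0 / crosshead_speed`` (about 12.7 s for the
    defaults), then holds while the load cell samples at
    ``sampling_rate`` for ``duration`` seconds total.

    ``fluid_fraction`` sets the peak of the summed channel (fluid)
    contribution as a fraction of the elastic stress ``E * strain0`` —
    the absolute partitioning between matrix and channels is not
    physically constrained here, so it is an explicit knob.
    ``noise_sd`` is additive Gaussian load noise in Pa; a seed is
    mandatory whenever it is nonzero.
    """

    fluid: Fluid
    block: TissueBlock = field(default_factory=default_block)
    channels: tuple[ChannelSpec, ...] = field(default_factory=default_channels)
    strain0: float = 0.05
    crosshead_speed: float = 1.5e-4
    duration: float = 500.0
    sampling_rate: float = 10.0
    fluid_fraction: float = 0.10
    noise_sd: float = 0.0
    background_offset: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.channels) < 1:
            raise ValueError("need at least one channel")
        if not 0.0 < self.strain0 < 1.0:
            raise ValueError(f"strain0 must lie in (0, 1), got {self.strain0}")
        if self.crosshead_speed <= 0:
            raise ValueError(f"crosshead_speed must be > 0, got {self.crosshead_speed}")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be > 0")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when noise_sd > 0")
        if self.ramp_duration >= self.duration:
            raise ValueError("duration must exceed the ramp duration")

    @property
    def ramp_duration(self) -> float:
        """``T0 = strain0 * x0 / crosshead_speed`` (s)."""
        return self.strain0 * self.block.x0 / self.crosshead_speed

    @property
    def strain_program(self) -> StrainProgram:
        return StrainProgram(self.strain0, self.ramp_duration, self.duration)

    def times(self) -> np.ndarray:
        n = int(round(self.duration * self.sampling_rate)) + 1
        return np.arange(n) / self.sampling_rate

    def channel_taus(self) -> list[float]:
        return [
            channel_time_constant(self.fluid, ch, self.block) for ch in self.channels
        ]


def _channel_amplitude(config: PhantomExperimentConfig, tau: float) -> float:
    """Per-channel B0 such that the summed fluid-term peak (at t = T0)
    is ``fluid_fraction * E * strain0``."""
    t0 = config.ramp_duration
    peak_unit = tau * (1.0 - np.exp(-t0 / tau))
    total_peak = (
        config.fluid_fraction * config.block.youngs_modulus * config.strain0
    )
    return total_peak / (len(config.channels) * peak_unit)


def simulate_relaxation_trace(config: PhantomExperimentConfig) -> StressTrace:
    """Simulate one compression test: elastic background ``E * eps(t)``
    plus the ramp-plus-hold response of every channel, a constant
    offset, and seeded Gaussian load noise."""
    t = config.times()
    program = config.strain_program
    stress = config.block.youngs_modulus * program.strain(t)
    for tau in config.channel_taus():
        b0 = _channel_amplitude(config, tau)
        stress = stress + ramp_plus_hold_stress(
            RampHoldParams(b0, tau), config.ramp_duration, t
        )
    stress = stress + config.background_offset
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        stress = stress + rng.normal(0.0, config.noise_sd, size=t.size)
    return StressTrace(t, stress)


def simulate_paired_difference(
    config_fluid1: PhantomExperimentConfig,
    config_fluid2: PhantomExperimentConfig,
    delta_mismatch: float = 0.0,
) -> StressTrace:
    """Differenced pair of virtual tests: trace(fluid 2) - trace(fluid 1).

    Fluid 2 is conventionally the more viscous one, so the difference
    matches the two-fluid model's sign convention.  Both configurations
    must share geometry, strain program and sampling; the elastic
    background then cancels exactly in the noiseless limit.
    ``delta_mismatch`` adds a constant emulating small sample-to-sample
    offsets (the fitted ``delta``).
    """
    for attr in (
        "block",
        "channels",
        "strain0",
        "crosshead_speed",
        "duration",
        "sampling_rate",
    ):
        if getattr(config_fluid1, attr) != getattr(config_fluid2, attr):
            raise ValueError(f"paired configs must share {attr}")
    trace1 = simulate_relaxation_trace(config_fluid1)
    trace2 = simulate_relaxation_trace(config_fluid2)
    return StressTrace(trace1.times, trace2.stresses - trace1.stresses + delta_mismatch)


@dataclass(frozen=True)
class WaveSynthConfig:
    """A virtual two-location shear-wave acquisition.

    A Gaussian-spectrum velocity pulse (center ``pulse_center_hz``,
    spectral standard deviation ``pulse_bandwidth_hz``) is recorded at
    location 1; location 2, ``dx`` metres further from the push, sees
    the same pulse propagated through the dispersive medium
    ``c(f) = c' * f**a'`` (applied as the exact per-frequency phase
    delay ``exp(-i * 2*pi*f * dx / c(f))``).  ``noise_sd`` is additive
    Gaussian velocity noise relative to the peak of the clean pulse.
    """

    c_prime: float
    a_prime: float
    dx: float = 0.004
    sampling_rate: float = 10000.0
    duration: float = 0.25
    pulse_center_hz: float = 140.0
    pulse_bandwidth_hz: float = 55.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.c_prime <= 0:
            raise ValueError(f"c_prime must be > 0, got {self.c_prime}")
        if self.dx <= 0 or self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("dx, sampling_rate and duration must be > 0")
        if self.pulse_center_hz <= 0 or self.pulse_bandwidth_hz <= 0:
            raise ValueError("pulse center and bandwidth must be > 0")
        if self.pulse_center_hz + 3.0 * self.pulse_bandwidth_hz >= self.sampling_rate / 2:
            raise ValueError("pulse band exceeds the Nyquist frequency")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when noise_sd > 0")

    def phase_speed(self, f):
        """The generating dispersion law ``c(f) = c' * f**a'`` (m/s)."""
        return self.c_prime * np.asarray(f, dtype=float) ** self.a_prime


def simulate_wave_pair(config: WaveSynthConfig) -> WaveformPair:
    """Synthesize the two-location waveform pair for a dispersive medium."""
    n = int(round(config.duration * config.sampling_rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / config.sampling_rate)
    t_center = config.duration / 2.0
    spectrum = np.exp(
        -((freqs - config.pulse_center_hz) ** 2)
        / (2.0 * config.pulse_bandwidth_hz**2)
    ) * np.exp(-2j * np.pi * freqs * t_center)
    # per-frequency propagation delay dx / c(f); the DC bin carries no energy
    delay = np.zeros_like(freqs)
    delay[1:] = config.dx / config.phase_speed(freqs[1:])
    v1 = np.fft.irfft(spectrum, n)
    v2 = np.fft.irfft(spectrum * np.exp(-2j * np.pi * freqs * delay), n)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        sd = config.noise_sd * np.abs(v1).max()
        v1 = v1 + rng.normal(0.0, sd, size=n)
        v2 = v2 + rng.normal(0.0, sd, size=n)
    return WaveformPair(v1, v2, config.sampling_rate, config.dx)


def simulate_dispersion_measurements(
    c_prime: float,
    a_prime: float,
    band: tuple[float, float] = (60.0, 220.0),
    n_points: int = 15,
    n_sets: int = 4,
    noise_sd: float = 0.02,
    seed: int | None = None,
    condition: str | None = None,
) -> list[DispersionCurve]:
    """Seeded noisy realizations of a power-law dispersion curve.

    ``noise_sd`` is the fractional (relative) standard deviation of the
    multiplicative speed noise, e.g. 0.02 for 2% scatter.  The default
    structure — four baseline sets with (0.412, 0.242) or three
    vasoconstriction sets with (0.589, 0.257) — mirrors a typical
    perfused-placenta acquisition series.
    """
    if n_points < 3:
        raise ValueError(f"need at least 3 points per curve, got {n_points}")
    f_lo, f_hi = band
    if not 0 < f_lo < f_hi:
        raise ValueError(f"band must satisfy 0 < f_lo < f_hi, got {band}")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is mandatory when noise_sd > 0")
    freqs = np.linspace(f_lo, f_hi, n_points)
    truth = c_prime * freqs**a_prime
    rng = np.random.default_rng(seed) if noise_sd > 0 else None
    curves = []
    for _ in range(n_sets):
        speeds = truth.copy()
        if rng is not None:
            speeds = speeds * (1.0 + rng.normal(0.0, noise_sd, size=n_points))
        curves.append(DispersionCurve(freqs, np.maximum(speeds, 1e-12), condition))
    return curves
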