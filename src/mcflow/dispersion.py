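"""Shear-wave-speed dispersion: two-point phase-velocity estimation and power-law fits.

A radiation-force push launches a shear wave that is tracked at two
lateral locations separated by ``dx``.  For each frequency ``f`` the
cross-spectral phase difference ``dphi(f)`` between the two particle
velocity waveforms gives the phase velocity

    c(f) = 2 * pi * f * dx / dphi(f).

Under the microchannel flow model a power-law relaxation spectrum with
exponent ``b`` implies power-law dispersion of the shear wave speed,

    c_s(f) = c' * f**a',        a' = a / 2 = (b - 1) / 2,

so fitting ``(c', a')`` to a measured dispersion curve reads the
vasculature's power-law exponent off wave data, and the ratio of ``c'``
between two physiological states measures the stiffening caused by,
e.g., vasoconstriction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal.windows import hann

from .core import VasoScale, vaso_stress_scale
from .fitting import ConstantSeriesError, r_squared

__all__ = [
    "DispersionCurve",
    "PowerLawFit",
    "WaveformPair",
    "VasoComparisonReport",
    "two_point_phase_velocity",
    "fit_power_law",
    "condition_amplitude_ratio",
    "compare_vaso_prediction",
    "b_from_dispersion_exponent",
]


@dataclass(frozen=True)
class DispersionCurve:
    """Shear wave speed versus frequency, optionally tagged with the
    physiological condition it was measured under."""

    frequencies: np.ndarray
    speeds: np.ndarray
    condition: str | None = None

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        speeds = np.asarray(self.speeds, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "speeds", speeds)
        if freqs.size != speeds.size:
            raise ValueError("frequencies and speeds must have equal length")
        if freqs.size and (np.any(freqs <= 0) or np.any(np.diff(freqs) <= 0)):
            raise ValueError("frequencies must be positive and strictly increasing")
        if np.any(speeds <= 0):
            raise ValueError("speeds must be positive")

    def __len__(self) -> int:
        return int(self.frequencies.size)


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted dispersion power law ``c_s = c' * f**a'``.

    ``a'`` is half the relaxation-spectrum exponent ``a = b - 1``, so
    ``b = 2 a' + 1``.
    """

    c_prime: float
    a_prime: float
    r_squared: float
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.c_prime <= 0:
            raise ValueError(f"c_prime must be > 0, got {self.c_prime}")

    @property
    def b(self) -> float:
        """Implied relaxation-spectrum power-law exponent ``b = 2 a' + 1``."""
        return b_from_dispersion_exponent(self.a_prime)

    def speed(self, f):
        """Evaluate the fitted law at frequency(ies) ``f`` (Hz)."""
        return self.c_prime * np.asarray(f, dtype=float) ** self.a_prime


@dataclass(frozen=True)
class WaveformPair:
    """Particle-velocity waveforms at two locations a lateral distance
    ``dx`` apart, sampled at ``sampling_rate`` Hz."""

    v1: np.ndarray
    v2: np.ndarray
    sampling_rate: float
    dx: float

    def __post_init__(self) -> None:
        v1 = np.asarray(self.v1, dtype=float)
        v2 = np.asarray(self.v2, dtype=float)
        object.__setattr__(self, "v1", v1)
        object.__setattr__(self, "v2", v2)
        if v1.size != v2.size:
            raise ValueError("v1 and v2 must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.dx <= 0:
            raise ValueError(f"dx must be > 0, got {self.dx}")

    def __len__(self) -> int:
        return int(self.v1.size)


def two_point_phase_velocity(
    pair: WaveformPair,
    band: tuple[float, float] = (60.0, 220.0),
    amplitude_threshold: float = 0.1,
    window: bool = True,
) -> DispersionCurve:
    """Phase-velocity dispersion from the cross-spectrum of two waveforms.

    Both traces are (optionally) Hann-tapered and Fourier transformed;
    the cross-phase ``angle(V1 * conj(V2))`` is unwrapped along
    increasing frequency starting from the lowest in-band bin, and the
    phase velocity ``c(f) = 2*pi*f*dx / dphi(f)`` is returned on the
    in-band bins whose cross-spectral magnitude reaches
    ``amplitude_threshold`` times the in-band peak.

    Raises ``ValueError`` if the band lies outside (0, Nyquist), if the
    amplitude mask empties the band, or if the unwrapped phase is
    non-positive across the whole band (waveform 2 must lag waveform 1).
    """
    f_lo, f_hi = band
    nyquist = pair.sampling_rate / 2.0
    if not 0.0 < f_lo < f_hi < nyquist:
        raise ValueError(
            f"band {band} must satisfy 0 < f_lo < f_hi < Nyquist ({nyquist} Hz)"
        )
    n = len(pair)
    taper = hann(n, sym=False) if window else np.ones(n)
    spec1 = np.fft.rfft(pair.v1 * taper)
    spec2 = np.fft.rfft(pair.v2 * taper)
    freqs = np.fft.rfftfreq(n, d=1.0 / pair.sampling_rate)
    cross = spec1 * np.conj(spec2)

    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    if not np.any(in_band):
        raise ValueError("no frequency bins fall inside the requested band")
    phase = np.unwrap(np.angle(cross[in_band]))
    magnitude = np.abs(cross[in_band])
    f_sel = freqs[in_band]

    if np.all(phase <= 0):
        raise ValueError(
            "cross-phase is non-positive across the band: waveform 2 does not "
            "lag waveform 1 (check the ordering of the two locations)"
        )
    keep = (magnitude >= amplitude_threshold * magnitude.max()) & (phase > 0)
    if not np.any(keep):
        raise ValueError("amplitude masking removed every in-band frequency bin")
    speeds = 2.0 * np.pi * f_sel[keep] * pair.dx / phase[keep]
    return DispersionCurve(f_sel[keep], speeds)


def fit_power_law(
    curve: DispersionCurve,
    method: str = "loglog",
    condition: str | None = None,
) -> PowerLawFit:
    """Least-squares fit of ``c_s = c' * f**a'`` to a dispersion curve.

    ``method="loglog"`` (default) is closed-form linear regression of
    ``log c`` on ``log f``; ``method="nls"`` refines that estimate by
    direct nonlinear least squares in linear speed space.  Both are
    deterministic.  R^2 is reported in linear speed space.
    """
    if len(curve) < 3:
        raise ValueError(f"power-law fit requires at least 3 points, got {len(curve)}")
    log_f = np.log(curve.frequencies)
    log_c = np.log(curve.speeds)
    a_prime, log_c_prime = np.polyfit(log_f, log_c, 1)
    c_prime = float(np.exp(log_c_prime))
    a_prime = float(a_prime)
    if method == "nls":
        popt, _ = curve_fit(
            lambda f, c0, a0: c0 * f**a0,
            curve.frequencies,
            curve.speeds,
            p0=[c_prime, a_prime],
            maxfev=10000,
        )
        c_prime, a_prime = float(popt[0]), float(popt[1])
    elif method != "loglog":
        raise ValueError(f"unknown method {method!r}; use 'loglog' or 'nls'")
    predicted = c_prime * curve.frequencies**a_prime
    try:
        r2 = r_squared(curve.speeds, predicted)
    except ConstantSeriesError:
        r2 = float("nan")
    return PowerLawFit(
        c_prime=c_prime,
        a_prime=a_prime,
        r_squared=r2,
        condition=condition if condition is not None else curve.condition,
    )


def condition_amplitude_ratio(fit_post: PowerLawFit, fit_base: PowerLawFit) -> float:
    """Ratio ``c'_post / c'_base`` between two fitted dispersion amplitudes."""
    return fit_post.c_prime / fit_base.c_prime


def b_from_dispersion_exponent(a_prime: float) -> float:
    """Spectrum exponent from the dispersion exponent: ``b = 2 a' + 1``."""
    return 2.0 * a_prime + 1.0


@dataclass(frozen=True)
class VasoComparisonReport:
    """Model-predicted versus observed stiffening after a vessel-radius change.

    ``predicted_factor`` is the MCFM stress scale ``chi**(-4*(b-1))``;
    ``predicted_sqrt_factor`` is its square root, the factor that would
    apply to a wave *speed* if the stress scale is read as a modulus
    scale (``c_s`` is proportional to ``sqrt(E)``).  Both discrepancies
    against the observed ``c'`` ratio are reported rather than choosing
    one convention.
    """

    chi: float
    b: float
    predicted_factor: float
    predicted_sqrt_factor: float
    observed_ratio: float
    discrepancy: float
    discrepancy_sqrt: float


def compare_vaso_prediction(
    scale: VasoScale, b: float, fit_base: PowerLawFit, fit_post: PowerLawFit
) -> VasoComparisonReport:
    """Compare the MCFM vasoconstriction scale factor with the observed
    dispersion-amplitude ratio between two conditions."""
    predicted = vaso_stress_scale(scale, b)
    observed = condition_amplitude_ratio(fit_post, fit_base)
    return VasoComparisonReport(
        chi=scale.chi,
        b=b,
        predicted_factor=predicted,
        predicted_sqrt_factor=float(np.sqrt(predicted)),
        observed_ratio=observed,
        discrepancy=predicted - observed,
        discrepancy_sqrt=float(np.sqrt(predicted)) - observed,
    )
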