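"""Nonlinear least-squares fitting of stress-difference traces to the two-fluid model.

The model (see :mod:`mcflow.ramp_hold`) is a difference of two
ramp-plus-hold exponential responses plus an additive offset:

    delta_sigma(t) = rph(B2, tau2, t) - rph(B1, tau1, t) + delta

It is linear in ``(B1, B2, delta)`` at fixed time constants but strongly
multimodal in ``(tau1, tau2)``, so the fit proceeds in two stages:

1. a deterministic multi-start scan over a log-spaced ``(tau1, tau2)``
   grid, solving the linear subproblem exactly at each node
   (variable projection), and
2. full nonlinear refinement of the best-scoring starts with
   ``scipy.optimize.least_squares``, parameterizing the time constants
   on a log scale to keep them positive.

Results are reported in canonical order ``tau2 > tau1`` (the more
viscous fluid second).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .ramp_hold import RampHoldParams, TwoFluidDifferenceParams, ramp_plus_hold_stress

__all__ = [
    "StressTrace",
    "FitOptions",
    "DifferenceFitResult",
    "ConstantSeriesError",
    "r_squared",
    "fit_two_fluid_difference",
]


class ConstantSeriesError(ValueError):
    """The observed series is constant, so R^2 is undefined."""


@dataclass(frozen=True)
class StressTrace:
    """A sampled stress-versus-time record.

    Times must be finite and strictly increasing, stresses finite, and
    both at least two samples long (the fit itself demands more; see
    :func:`fit_two_fluid_difference`).
    """

    times: np.ndarray
    stresses: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        stresses = np.asarray(self.stresses, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "stresses", stresses)
        if times.ndim != 1 or stresses.ndim != 1:
            raise ValueError("times and stresses must be one-dimensional")
        if times.size != stresses.size:
            raise ValueError(
                f"length mismatch: {times.size} times vs {stresses.size} stresses"
            )
        if times.size < 2:
            raise ValueError(f"a stress trace needs at least 2 samples, got {times.size}")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(stresses))):
            raise ValueError("times and stresses must be finite")
        steps = np.diff(times)
        if np.any(steps <= 0):
            bad = int(np.argmax(steps <= 0)) + 1
            raise ValueError(
                f"times must be strictly increasing; first violation at row {bad} "
                f"(t={times[bad]!r} after t={times[bad - 1]!r})"
            )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class FitOptions:
    """Options controlling the two-fluid difference fit.

    The time-constant scan grid is log-spaced with ``points_per_decade``
    nodes per decade over ``[tau_grid_min, tau_grid_max]`` seconds; the
    ``n_refine`` best grid nodes are polished with the nonlinear
    optimizer under ``cost_tol`` / ``max_nfev``.  Setting
    ``nonnegative_amplitudes`` constrains both ``B`` values to be >= 0.
    """

    tau_grid_min: float = 0.1
    tau_grid_max: float = 1000.0
    points_per_decade: int = 6
    n_refine: int = 8
    cost_tol: float = 1e-10
    max_nfev: int = 2000
    nonnegative_amplitudes: bool = False

    def tau_grid(self) -> np.ndarray:
        n_decades = np.log10(self.tau_grid_max / self.tau_grid_min)
        n = int(round(n_decades * self.points_per_decade)) + 1
        return np.geomspace(self.tau_grid_min, self.tau_grid_max, n)


@dataclass(frozen=True)
class DifferenceFitResult:
    """Fitted two-fluid difference parameters with fit diagnostics.

    ``r_squared`` is NaN when the observed trace is constant (the
    coefficient of determination is undefined there); ``converged``
    reports whether any refinement start converged.
    """

    params: TwoFluidDifferenceParams
    r_squared: float
    residual_norm: float
    n_starts_used: int
    converged: bool

    @property
    def tau_ratio(self) -> float:
        """``tau2 / tau1`` — tracks the viscosity ratio of the two fluids."""
        return self.params.tau2 / self.params.tau1


def r_squared(observed, predicted) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``.

    ``SS_tot`` is taken about the mean of the observations.  Raises
    :class:`ConstantSeriesError` when the observed series is constant.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size != predicted.size:
        raise ValueError("observed and predicted must have equal length")
    if observed.size < 2:
        raise ValueError("need at least 2 points")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ConstantSeriesError("observed series is constant; R^2 is undefined")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def _unit_rph(tau: float, ramp_duration: float, t: np.ndarray) -> np.ndarray:
    return ramp_plus_hold_stress(RampHoldParams(1.0, tau), ramp_duration, t)


def _linear_solve(tau1, tau2, ramp_duration, t, y, nonneg):
    """Best (B1, B2, delta) at fixed time constants, plus the SSR."""
    g1 = _unit_rph(tau1, ramp_duration, t)
    g2 = _unit_rph(tau2, ramp_duration, t)
    design = np.column_stack([-g1, g2, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    if nonneg:
        coef[:2] = np.maximum(coef[:2], 0.0)
    resid = design @ coef - y
    return coef, float(resid @ resid)


def fit_two_fluid_difference(
    trace: StressTrace,
    ramp_duration: float,
    options: FitOptions | None = None,
) -> DifferenceFitResult:
    """Fit the five-parameter two-fluid stress-difference model to a trace.

    The trace must span both the ramp (t < T0) and hold phases and hold
    at least 8 samples.  The fit is deterministic for fixed options.
    Non-convergence of every refinement start yields a flagged result
    (``converged=False``), not an exception.
    """
    options = options or FitOptions()
    if ramp_duration <= 0:
        raise ValueError(f"ramp_duration must be > 0, got {ramp_duration}")
    if len(trace) < 8:
        raise ValueError(f"fit requires at least 8 samples, got {len(trace)}")
    t = trace.times
    y = trace.stresses
    if t[0] >= ramp_duration or t[-1] <= ramp_duration:
        raise ValueError(
            "trace must span both the ramp and the hold phase "
            f"(T0={ramp_duration} s, trace covers [{t[0]}, {t[-1]}] s)"
        )

    # Stage 1: variable-projection scan over the (tau1, tau2) grid.
    grid = options.tau_grid()
    scored: list[tuple[float, float, float, np.ndarray]] = []
    for i, tau1 in enumerate(grid):
        for tau2 in grid[i + 1 :]:
            coef, ssr = _linear_solve(
                tau1, tau2, ramp_duration, t, y, options.nonnegative_amplitudes
            )
            scored.append((ssr, tau1, tau2, coef))
    scored.sort(key=lambda item: item[0])
    starts = scored[: options.n_refine]

    # Stage 2: nonlinear refinement; log-parameterized time constants.
    if options.nonnegative_amplitudes:
        lower = [-np.inf, -np.inf, 0.0, 0.0, -np.inf]
        upper = np.inf
    else:
        lower, upper = -np.inf, np.inf

    def residuals(x):
        log_tau1, log_tau2, b1, b2, delta = x
        tau1, tau2 = np.exp(log_tau1), np.exp(log_tau2)
        model = (
            _unit_rph(tau2, ramp_duration, t) * b2
            - _unit_rph(tau1, ramp_duration, t) * b1
            + delta
        )
        return model - y

    best = None
    any_converged = False
    for ssr, tau1, tau2, coef in starts:
        x0 = np.array([np.log(tau1), np.log(tau2), coef[0], coef[1], coef[2]])
        sol = least_squares(
            residuals,
            x0,
            bounds=(lower, upper),
            ftol=options.cost_tol,
            xtol=options.cost_tol,
            gtol=options.cost_tol,
            max_nfev=options.max_nfev,
        )
        any_converged = any_converged or bool(sol.success)
        if best is None or sol.cost < best.cost:
            best = sol

    log_tau1, log_tau2, b1, b2, delta = best.x
    tau1, tau2 = float(np.exp(log_tau1)), float(np.exp(log_tau2))
    b1, b2, delta = float(b1), float(b2), float(delta)
    if tau1 > tau2:  # canonical order: slower (more viscous) component second
        tau1, tau2 = tau2, tau1
        b1, b2 = -b2, -b1
    params = TwoFluidDifferenceParams(
        b1=b1, tau1=tau1, b2=b2, tau2=tau2, delta=delta, ramp_duration=ramp_duration
    )
    predicted = y + best.fun
    try:
        r2 = r_squared(y, predicted)
    except ConstantSeriesError:
        r2 = float("nan")
    return DifferenceFitResult(
        params=params,
        r_squared=r2,
        residual_norm=float(np.linalg.norm(best.fun)),
        n_starts_used=len(starts),
        converged=any_converged,
    )
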