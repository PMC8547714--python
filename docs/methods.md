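# Methods

## Model

The microchannel flow model (MCFM) treats a fluid-filled channel in an
elastic matrix as a series spring–dashpot element. Poiseuille's law for
laminar flow, ΔP = 8ηLQ/(πr⁴), combined with the proportionality
ΔP ≅ C₁σₓ between the channel pressure drop and the applied normal
stress, yields a dashpot whose stress-relaxation time constant is

τ = η A₀′ x₀ / (C r⁴ E),  C = C₁π/(8L).

C₁ defaults to 1 (the bare geometric constant π/8L reproduces the
phantom's numerically evaluated time constant) and is configurable on
`ChannelSpec`. A vasculature is modelled as a continuum of such
channels with a power-law spectrum of time constants; integrating the
exponential kernel A₀ τ⁻ᵇ e^(−t/τ) over τ ∈ (0, ∞) gives the
two-parameter relaxation A₀ t^(1−b) Γ(b−1), and over τ ∈ (T_min, T_max)
the four-parameter incomplete-gamma form implemented in
`bounded_relaxation_stress`. Γ(a, x) is always the non-regularized
upper incomplete gamma; scipy's regularized `gammaincc` is multiplied
back by Γ(a).

**Spectrum kernel convention.** The spectrum is written A(τ) = A₀τ⁻ᵇ
(negative exponent): this is the convention under which the
closed forms above are the exact Laplace-type transforms of the
spectrum, which both the quadrature-equivalence tests and the
bounded→unbounded limit verify to 1e−6 relative. A positive-exponent
kernel is not consistent with those closed forms and is not offered.

**Working domain.** 1 < b < 2, so Γ(b−1) is finite and the spectral
integrals converge at both ends; values outside are rejected rather
than analytically continued. The closed forms are undefined at t = 0;
all relaxation evaluations require t > 0 and samplers start at the
first grid point after zero where needed.

**Vasoconstriction transformation.** Scaling every vessel radius by χ
maps each time constant as τ → τ/χ⁴ (τ ∝ r⁻⁴), so T_min and T_max are
divided by χ⁴ and, for the power-law spectrum, the amplitude maps as
A₀ → A₀·χ^(−4(b−1)) with b unchanged (b encodes branching geometry,
not calibre). Consequently the relaxation stress of the constricted
state is the baseline closed form with mapped bounds multiplied by
χ^(−4(b−1)) — 1/χ² at b = 1.5 — which `transform_spectrum` /
`vaso_stress_scale` implement and a self-consistency test enforces at
machine precision. χ itself is obtained from perfusion pressures at
constant flow via χ = (ΔP₁/ΔP₂)^(1/4).

## Ramp-plus-hold synthesis

A test machine applies strain as a ramp of duration T₀ followed by a
hold. For a linear material the ramp response is the running integral
of the ideal step response B₀e^(−t/τ), giving B₀τ(1 − e^(−t/τ)), and
the ramp-plus-hold response is ramp(t) − ramp(t − T₀)·H(t − T₀)
(Heaviside with H(0) = 1; immaterial because ramp(0) = 0). B₀ carries
Pa/s and absorbs the modulus, ramp slope and channel count; fitted B
values are not decomposed into physical constants. Differencing two
samples that share geometry but carry fluids of different viscosity
cancels the elastic background E·ε(t) exactly; an additive constant δ
absorbs sample-to-sample offsets.

## Difference fitting

The five-parameter model B₂·rph(τ₂) − B₁·rph(τ₁) + δ is multimodal in
(τ₁, τ₂) but linear in (B₁, B₂, δ). The fit therefore scans a
log-spaced τ grid (default 6 points/decade over 0.1–1000 s, all pairs
τ₁ < τ₂), solves the linear subproblem exactly at each node (variable
projection), and polishes the best 8 starts with
`scipy.optimize.least_squares` on (log τ₁, log τ₂, B₁, B₂, δ) —
log-parameterization keeps the time constants positive without bounds.
Convergence tolerances are 1e−10 with at most 2000 evaluations per
start; all defaults sit on `FitOptions`. Amplitudes are unconstrained
in sign by default with an opt-in non-negativity constraint. Results
are always reported with τ₂ ≥ τ₁ (the more viscous component second);
a constant input trace returns B ≈ 0 with R² flagged NaN
(undefined), not an exception. T₀ is measured by the test machine and
supplied, never fitted. No weighting is applied; residuals are plain
(the data carry homoscedastic load noise).

## Dispersion estimation and fitting

Two particle-velocity waveforms a lateral distance Δx apart are
Hann-tapered (configurable off), Fourier transformed, and the
cross-phase angle(V₁·conj V₂) is unwrapped along increasing frequency
starting from the lowest in-band bin; the phase velocity is
c(f) = 2πfΔx/Δφ(f). Bins below 10% of the in-band peak cross-spectral
magnitude are masked; a non-positive unwrapped phase across the whole
band (waveform 2 not lagging waveform 1) is a signalled error. The
default band is 60–220 Hz, a typical push-pulse tracking band, and the
default Δx = 4 mm keeps the lowest in-band phase below π so the
unwrapping start is unambiguous.

The power law c_s = c′·f^a′ is fitted by closed-form linear regression
in log–log space (deterministic); an optional nonlinear refinement in
linear speed space is available, and the pipeline reports both when
they disagree by more than 1%. R² is computed in linear speed space.
Note that c′ is the intercept extrapolated to 1 Hz, far below the
measurement band, so its single-realization scatter under noise is
several times the per-point noise level; recovery claims are therefore
made on replicate averages. The comparison of a vasoconstriction
prediction with data reports both the stress/modulus scale χ^(−4(b−1))
and its square root (the wave-speed factor if c_s ∝ √E), with the
discrepancy from the observed c′ ratio for each, rather than asserting
one convention.

## Synthetic data

The generators emulate two laboratory settings:

* **Virtual phantom compression** — a 35 × 35 × 38 mm gelatin block
  (E = 7 kPa) with six identical 3 mm-diameter, 32 mm channels,
  compressed to 5% strain at 0.15 mm/s crosshead speed, so
  T₀ = ε₀x₀/v = 12.67 s; sampled at 10 Hz for 500 s. The trace is
  E·ε(t) plus the ramp-plus-hold term of each channel (τ from the
  dashpot law) plus offset and additive i.i.d. Gaussian load noise.
  Channel amplitudes are set so the summed fluid-term peak is a
  configurable fraction (default 10%) of the elastic stress E·ε₀ —
  the absolute matrix/channel partitioning is not physically
  constrained, so it is an explicit knob. The default load noise of
  0.4 Pa (≈0.5 mN on the 12.25 cm² face, a realistic figure for a 5 N
  load cell) puts difference-fit R² in the high-0.8s-to-high-0.9s
  range typical of such tests.
* **Virtual wave tracking** — a Gaussian-spectrum pulse (center 140 Hz,
  spectral sd 55 Hz) at location 1; location 2 receives the same pulse
  propagated through c(f) = c′·f^a′ applied as the exact per-frequency
  phase delay. Dispersion *curves* are generated directly on a fixed
  frequency grid with multiplicative Gaussian scatter (relative sd,
  default 2%); the default study structure is four baseline sets at
  (c′, a′) = (0.412, 0.242) and three vasoconstriction sets at
  (0.589, 0.257).

All generators are pure functions of config + seed (bitwise
reproducible; a seed is mandatory whenever noise is requested). What
they do **not** model: gelatin curing/aging, 3-D stress fields,
channel–channel interaction (superposition is linear), load-cell
quantization, scanner noise physics, or radiation-force wave
excitation — so passing tests demonstrate correctness of the analysis
chain under the model's own assumptions, not robustness to every
artifact of real acquisitions.

## Numerical choices and limitations

* Quadrature oracles use adaptive `scipy.integrate.quad` with 500
  subdivisions; closed forms agree to 1e−6 relative across
  b ∈ {1.1 … 1.9} × t ∈ logspace(−1, 3).
* Truncating the spectrum 6 decades beyond t leaves a relative tail
  error of 2/√π × 10⁻³ at b = 1.5; the bounded form converges to the
  unbounded one at that rate, not faster.
* Degenerate spectrum interval (T_min → T_max) yields zero stress; the
  constructor rejects T_min ≥ T_max.
* Fit identifiability requires well-separated time constants
  (τ₂/τ₁ ≳ 5) and a trace spanning both ramp and hold; closely spaced
  τ's trade off against the B's and recovery degrades gracefully.
* Problem sizes throughout (5001-point traces, 2500-sample waveforms,
  20-replicate recovery experiments) were chosen so every property is
  statistically meaningful while the full suite completes in seconds.
* SI units internally; mmHg and cSt only at explicit converter
  boundaries. CSV is the sole interchange format, with JSON sidecars
  for provenance (config + seed) on every generated file.
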