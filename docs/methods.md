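# Methods

This note documents the models implemented in `clawmech`, the parameter
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions made where the underlying
method descriptions left the design open.

## Non-local means denoising

The patch distance `D(i,j)` is the Gaussian-kernel-weighted **mean** squared
intensity difference between the patches around pixels i and j (kernel
normalized to sum 1, SD `kernel_sd` = 1.5 px over a 7×7 patch by default).
Weights are `exp(−D/h²)` (original scheme) or
`exp(−D/h₁²)·cos(πD/2h₂)` for `D ≤ h₂`, zero beyond (improved scheme); the
improved weight is continuous at the cutoff because the cosine factor
reaches zero exactly at `D = h₂`.

Conventions, each of which materially affects output:

- **Single normalization.** Raw kernel weights are normalized once by
  `C(i) = Σⱼ w(i,j)`. Formulations that place `1/C(i)` inside the weight
  *and* normalize again break `Σw = 1`; the single-normalization reading is
  used and the weight-sum property is exercised implicitly by the
  brute-force oracle tests.
- **Self-weight.** `w(i,i)` is set to the maximum of the other weights in
  the search window (standard NLM practice); the raw `D = 0` weight would
  over-trust the noisy centre pixel.
- **Borders.** Mirror (symmetric) padding.
- **Defaults.** 7×7 patches, 21×21 search window, `h = h₁ = 10·σ̂` with σ̂
  the wavelet-based noise estimate, and `h₂ = 3h²` (h₂ lives on the squared
  scale of D). These follow the classical NLM parameterisation; no tuning
  beyond it was done.

The fast implementation vectorises over window offsets; a literal
quadruple-loop implementation in the test suite is the oracle, and the two
agree to ~1e−13 in float and exactly after 8-bit rounding.

## Wavelet modulus-maxima edge detection

The transform is the canonical undecimated dyadic construction: cubic
B-spline binomial smoothing `[1,3,3,1]/8` dilated à trous between levels,
with first-difference detail filters, so WT¹/WT² approximate ∂x/∂y of the
smoothed image. The description this implements named only "B-spline
wavelets" at dyadic scales; the cubic-order, undecimated choice is the
standard modulus-maxima construction and is documented rather than inferred
from results.

- **Direction bins.** Gradient angles are quantized modulo 180° to
  0°/45°/90°/135°; exact midpoints round to the lower-angle bin.
- **Suppression tie rule.** A pixel survives iff its modulus is `>=` the
  neighbour on the negative side of its gradient direction and strictly `>`
  the neighbour on the positive side. The asymmetry prevents equal-valued
  plateaus from being kept twice (an interior plateau is dropped
  entirely); the one-pixel border is excluded.
- **Threshold λ.** Default `0.2 × max modulus` per scale, overridable with
  a global absolute λ. Cross-scale edge-count comparisons are only
  meaningful under a global λ: with per-scale relative thresholds, impulse
  noise inflates the fine-scale maximum and deflates its edge count.

On a noiseless disk phantom the j=1 detector localizes the boundary within
one pixel; the even-length detail filter contributes a half-pixel phase
that is absorbed by this tolerance.

## Boundary modelling

Edge maps are traced into ordered chains by greedy 8-connected walks
(endpoints preferred as starts; closed rings are rotated to begin at their
leftmost pixel so the strictly-x-monotone split yields two clean arcs).
Fitting families: 2nd-order Gaussian, 2nd-order Fourier
(`a0 + a1 cos xw + b1 sin xw + a2 cos 2xw + b2 sin 2xw`), and quadratic /
cubic polynomials; goodness is `R² = 1 − SSE/SST` with `SST = 0` a hard
error. Model selection takes the highest R², breaking exact ties toward
fewer parameters.

Nonlinear fits are multimodal, so initialization is explicit: the Fourier
frequency `w` is seeded from the dominant FFT peak of linearly detrended
data (with ×½ and ×2 fallbacks and a floor of half a period per data span),
amplitudes from linear least squares at fixed w, then a full 6-parameter
refinement; fitted `w < 0` is canonicalised to `w > 0` by flipping the sine
coefficients. Gaussian centres are seeded at the two largest local maxima.
Convergence failures are reported in the `FitResult`, never silently
swallowed. Coefficient standard errors come from the Gauss–Newton
covariance `s²(JᵀJ)⁻¹` with a finite-difference Jacobian.

Curvature uses analytic derivatives of the fitted closed form,
`K = |y″|/(1+y′²)^{3/2}`; "concave" means `y″ < 0` throughout the profiled
range, "convex" `y″ > 0`, else "mixed". Reference Fourier coefficients for
the four claw feature curves are packaged (`CLAW_FEATURE_CURVES`) so
curvature profiling runs without raw boundary extractions; their reported
narrative curvature bound for curve 1 (~1e−17 µm⁻¹) is *not* reproduced by
the formula applied to those same coefficients near x = 0 — the evaluation
domain or units behind that figure are unknown, so nothing asserts it.
Segment breakpoints, when not given, are suggested at the real roots of the
second derivative of a degree-(n+2) polynomial fit (three breakpoints →
quintic), which is deterministic and robust to moderate noise.

## Adhesion mechanics

Rigid-body statics only, matching the modelling level of the source
analysis: no contact elasticity, no pad (van der Waals) adhesion, no
dynamics. The regular closed form `θ = arctan μ − α` is the canonical
load-angle implementation; the equivalent ratio form
`tanθ = (μcosα − sinα)/(cosα + μsinα)` is retained as a test cross-check.
The two-contact system is solved as a 2×2 linear system in (N₁, N₂) rather
than through the chained closed forms, which carry sign ambiguities around
the N₁ = 0 crossing; the closed-form `k = N₁/N₂` expression is kept as an
independent check and agrees to machine precision. Past the limit angle
N₁ is reported negative with a `beyond_limit` flag rather than clamped.
`μcosα = sinα` (the friction-cone boundary) is a genuine singularity of the
horizontal equation and raises; sweep tables flag singular rows instead of
failing. Note that for the worked case (α = 45°, μ = 0.5) N₂ is increasing
in θ only up to `arctan(cv/|cp|) ≈ 71.6°` — monotonicity claims are tested
on the grasping range θ ≤ 60°. Angles are radians in the API, degrees in
CSV tables.

## Nanoindentation

Constants not fixed by the measurement description use standard
Oliver–Pharr values: β = 1.034 (Berkovich), ε = 0.75 (power-law unloading),
ideal area `A_c = 24.56 h_c²` with an optional first-order blunt-tip
correction `+2πR_tip h_c` (R_tip = 200 nm), diamond indenter
(E_i = 1140 GPa, ν_i = 0.07) and specimen ν = 0.3. The unloading power law
is fitted to the top 50% of the unloading branch *in dimensionless units*
(h/h_max, P/P_max); without this rescaling the prefactor B (order 1e9 in
SI) dwarfs h_f (order 1e−7) and the optimizer stalls on a local plateau.
Fits with exponent m outside [1, 3] are rejected as unphysical. The peak
load is taken as the mean over the hold plateau, not the record maximum,
which is biased upward by ~3σ under per-sample load noise. Because
"modulus" summaries of cuticle are ambiguous between E_r and the
specimen-side E, both are always reported.

## Synthetic-data generator

The generator defines the study conditions for every test:

- **Phantom.** The region between two non-crossing 2nd-order Fourier
  contours, scanline-rasterized at 256×256 by default (foreground 180,
  background 60), optionally Gaussian-blurred. The true contours are
  returned with the image, giving an exact boundary oracle; rasterized
  area matches the analytic polygon area within 2% at this resolution.
- **Noise.** "Snowflake" SEM speckle is modelled as additive Gaussian noise
  (SD 10 intensity units) plus 2% salt-and-pepper impulses. The real
  artefact was never characterised statistically; this mix reproduces its
  qualitative look (grain plus bright/dark flecks) while staying standard.
  One seeded `numpy` generator per call makes corruption bit-reproducible.
- **Indentation curves.** Trapezoidal protocol (3 mN peak, 50 µN/s load and
  unload, 50 s hold, 10 Hz sampling), Hertz-like `P ∝ h²` loading, and
  power-law unloading (m = 1.2) constructed so that Oliver–Pharr analysis
  of the noiseless curve returns the prescribed (H, E_r) — verified to
  within 2% across H ∈ {0.05, 0.1, 0.2} × E_r ∈ {0.5, 1.0, 1.5} GPa, and
  in practice to ~1e−6 %. (H, E_r) pairs whose implied final depth is
  negative are rejected as inconsistent. Hold-period creep is a linear
  drift, default zero.

What the generator does **not** emulate: SEM physics (charging, topographic
contrast, detector nonlinearity), cuticle layering (exo/endocuticle fibre
structure), correlated or signal-dependent noise, thermal drift and frame
compliance in indentation, and the irregular outline of a real claw beyond
two smooth Fourier arcs. Passing tests therefore demonstrate correctness of
the algorithms under controlled conditions, not performance claims on real
SEM images — in particular the absolute PSNR/R²/H/E values on synthetic
data do not transfer to the unavailable originals, only the internal
consistencies and orderings do.

## Problem sizes

The default verification sizes are: 10 seeded 128×128 phantoms for the
denoising benchmark, 16×16 images for brute-force NLM equivalence, 100
replicates of n = 200 samples for Fourier parameter recovery, a 90×90
(θ, α) grid for force-balance residuals, the 3×3 (H, E_r) grid for
indentation round trips, and a radius-30 disk in a 128×128 frame for edge
localization. These sizes give stable statistics for every property
checked while keeping a full run inexpensive.

## Known limitations

- The boundary tracer is greedy; at junction pixels it follows a fixed
  neighbour order and may split branched skeletons arbitrarily.
- The LoG zero-crossing detector uses a simple slope gate, not hysteresis.
- Automatic indentation segment splitting assumes a clean trapezoidal
  protocol; heavily drifting holds need explicit segment labels.
- The improved-NLM weight is used unnormalized inside the same
  normalization as the original scheme; if all non-self weights cut off,
  the pixel is returned unchanged.
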