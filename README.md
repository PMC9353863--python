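# clawmech

Structure–function analysis of insect claws, built as a tested, reusable
Python pipeline. Beetle and weevil claws grip rough surfaces with adhesion
forces that can exceed sixty times body weight; understanding how comes down
to (i) extracting the claw's boundary geometry from noisy SEM-style imagery,
(ii) modelling the claw-tip/asperity contact mechanics, and (iii) measuring
the cuticle's mechanical properties by nanoindentation. `clawmech`
implements all three stages, plus a synthetic-data generator with known
ground truth, so every stage is verifiable without access to raw microscopy
or indentation records. It is aimed at researchers in insect biomechanics
and bio-inspired (wall-climbing) robotics.

## What it computes

**Denoising.** Non-local means (NLM): each pixel becomes a weighted average
over a search window, `NL[v](i) = Σⱼ w(i,j) v(j) / Σⱼ w(i,j)`, with weights
driven by the Gaussian-weighted patch distance `D(i,j)`. Two weighting
schemes: the classical `w = exp(−D/h²)` and an improved weight
`w = exp(−D/h₁²)·cos(πD/2h₂)` for `D ≤ h₂` (0 beyond), which decays faster
and rejects dissimilar or impulse-contaminated patches outright. Quality is
scored by MSE and 8-bit PSNR = 10·log₁₀(255²/MSE).

**Edge detection.** An undecimated (à-trous) B-spline wavelet transform
yields per-scale detail fields (WT¹, WT²) ≈ the smoothed image gradient at
scale a = 2ʲ. Edges are modulus maxima of `√(|WT¹|²+|WT²|²)` along the
gradient direction (quantized to 0°/45°/90°/135°), then thresholded at λ.
Sobel, Roberts, Prewitt, LoG and Canny baselines are included for
comparison.

**Boundary modelling.** Edge maps are traced into ordered point chains and
segmented into feature curves; each segment is fitted by least squares with
four candidate families (2nd-order Gaussian, 2nd-order Fourier, 2nd/3rd
order polynomials), scored by R² = 1 − SSE/SST, and profiled by the
curvature of the fitted closed form, `K = |y″| / (1 + y′²)^{3/2}`, with
concave/convex classification by the sign of y″.

**Adhesion mechanics.** The claw tip (radius r) grasping asperities
(radius R, spacing d) self-locks when the pressure angle α satisfies
α < arctan μ; the sustainable load angle is θ = arctan μ − α. For the
two-particle contact the equilibrium
`F sinθ = (N₁−N₂)(μcosα−sinα)`, `F cosθ = (N₁+N₂)(μsinα+cosα)` is solved
for the contact normals, with the limit load angle
`θ_limit = arctan((tanα−μ)/(1+μtanα))` marking where N₁ crosses zero.

**Nanoindentation.** Oliver–Pharr analysis of load–displacement curves:
power-law fit `P = B(h−h_f)^m` of the unloading branch gives the stiffness
S, contact depth `h_c = h_max − ε P_max/S`, Berkovich area `A_c = 24.56 h_c²`,
then `H = P_max/A_c`, `E_r = √π S / (2β√A_c)` and the specimen modulus from
`1/E_r = (1−ν²)/E + (1−ν_i²)/E_i`.

## Worked example

```python
import math
from clawmech import (benchmark_schemes, force_distribution,
                      limit_load_angle, generate_indentation_curve,
                      analyze_curve)

# denoise a noisy claw phantom with both NLM schemes (seed 0)
print(benchmark_schemes(seed=0))
# {'psnr_noisy': 20.90, 'psnr_original': 25.82, 'psnr_improved': 26.28}

# two-contact force balance for the worked case: alpha 45 deg, mu 0.5, F 3 N
fb = force_distribution(3.0, math.radians(10), math.radians(45), 0.5)
print(round(fb.N1, 3), round(fb.N2, 3))          # 0.656 2.129
print(round(math.degrees(limit_load_angle(math.radians(45), 0.5)), 3))
# 18.435  -> N1 vanishes here; past it the upper particle carries the claw

# synthesize an indentation record with known properties and recover them
r = analyze_curve(generate_indentation_curve(0.197e9, 1.105e9))
print(round(r.H / 1e9, 3), round(r.E_r / 1e9, 3))  # 0.197 1.105
```

The PSNR numbers say the improved weighting denoises the phantom ~0.45 dB
better than classical NLM at these noise settings; the force balance shows
the lower contact shedding load as the load angle grows; the indentation
round trip recovers the prescribed hardness and reduced modulus from the
simulated curve.

The same operations are scriptable from a shell:

```bash
clawmech simulate --size 256 --out noisy.png --clean-out clean.png
clawmech denoise --scheme improved --in noisy.png --out dn.png \
    --reference clean.png --report metrics.json
clawmech edges --method wavelet --scales 1,2 --in dn.png --out edges_j{j}.png
clawmech adhesion --relationship forces_vs_theta --out sweep.csv
clawmech run --seed 1 --out-dir run1     # full pipeline + manifest
```

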