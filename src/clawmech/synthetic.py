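"""Synthetic inputs for the claw structure-function pipeline.

Real SEM images of weevil claws and the raw nanoindentation records are not
publicly deposited, so every pipeline stage is exercised on synthetic data
with known ground truth:

* a claw-like phantom image — the region between two smooth second-order
  Fourier contours, rendered by scanline polygon fill, optionally blurred;
* "snowflake" SEM-style noise modelled as additive Gaussian noise plus
  salt-and-pepper impulses;
* boundary point samples drawn from a known Fourier curve;
* trapezoidal-protocol indentation load-displacement curves whose unloading
  branch is constructed so that Oliver-Pharr analysis recovers prescribed
  hardness H and reduced modulus E_r.

All randomness flows through one ``numpy`` generator seeded per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as _sk_polygon

from .boundary import BoundaryPointSet, FourierModel

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "IndentationProtocol",
    "ClawPhantom",
    "default_phantom_spec",
    "generate_claw_phantom",
    "add_noise",
    "sample_boundary_points",
    "generate_indentation_curve",
]


# ---------------------------------------------------------------------------
# Phantom image
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Claw phantom: the filled region between two Fourier contours.

    Contours are y(x) in pixel coordinates (y = row index); the outer
    contour must stay strictly above the inner one across the window.
    """

    image_height: int = 256
    image_width: int = 256
    outer_curve: FourierModel = None
    inner_curve: FourierModel = None
    foreground: int = 180
    background: int = 60
    smoothing_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.image_height < 32 or self.image_width < 32:
            raise ValueError("phantom must be at least 32x32 pixels")
        for v in (self.foreground, self.background):
            if not (0 <= v <= 255):
                raise ValueError("intensities must lie in [0, 255]")
        if self.smoothing_sd < 0:
            raise ValueError("smoothing_sd must be >= 0")


def default_phantom_spec(height: int = 256, width: int = 256,
                         **overrides) -> PhantomSpec:
    """Default claw-like phantom scaled to the requested window.

    The contours are gentle half-period sine arcs (with a weak second
    harmonic on the outer contour for claw-like asymmetry) spanning the
    image width; the enclosed band mimics a claw silhouette in profile.
    """
    w = np.pi / width
    outer = FourierModel(a0=0.27 * height, a1=0.0, b1=0.51 * height,
                         a2=0.0, b2=-0.06 * height, w=w)
    inner = FourierModel(a0=0.16 * height, a1=0.0, b1=0.39 * height,
                         a2=0.0, b2=0.0, w=w)
    spec = PhantomSpec(image_height=height, image_width=width,
                       outer_curve=outer, inner_curve=inner)
    return replace(spec, **overrides) if overrides else spec


@dataclass
class ClawPhantom:
    """Rendered phantom plus the ground-truth contours used to draw it."""

    image: np.ndarray            # uint8, (H, W)
    outer_curve: FourierModel
    inner_curve: FourierModel
    x: np.ndarray                # column coordinates (pixels)
    outer_y: np.ndarray          # ground-truth outer contour rows
    inner_y: np.ndarray


def generate_claw_phantom(spec: Optional[PhantomSpec] = None) -> ClawPhantom:
    """Render the 8-bit phantom by scanline polygon fill.

    Raises ``ValueError`` if the two contours touch or cross anywhere in
    the rendered window (degenerate region).
    """
    if spec is None:
        spec = default_phantom_spec()
    outer, inner = spec.outer_curve, spec.inner_curve
    if outer is None or inner is None:
        raise ValueError("spec must define both outer and inner contours")

    H, W = spec.image_height, spec.image_width
    x = np.arange(W, dtype=float)
    y_out = outer.value(x)
    y_in = inner.value(x)
    if np.any(y_out <= y_in):
        raise ValueError(
            "outer and inner contours touch or cross inside the window; "
            "the enclosed region is degenerate")

    img = np.full((H, W), spec.background, dtype=float)
    # polygon: outer contour left->right, then inner contour right->left
    rows = np.concatenate([y_out, y_in[::-1]])
    cols = np.concatenate([x, x[::-1]])
    rr, cc = _sk_polygon(rows, cols, shape=(H, W))
    img[rr, cc] = spec.foreground

    if spec.smoothing_sd > 0:
        img = gaussian_filter(img, spec.smoothing_sd, mode="nearest")

    img8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ClawPhantom(image=img8, outer_curve=outer, inner_curve=inner,
                       x=x, outer_y=y_out, inner_y=y_in)


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """SEM-style 'snowflake' noise: additive Gaussian plus impulses.

    ``impulse_fraction`` of the pixels are replaced by 0 or 255 with equal
    probability after the Gaussian component is added.
    """

    gaussian_sd: float = 10.0
    impulse_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")
        if not (0 <= self.impulse_fraction <= 1):
            raise ValueError("impulse_fraction must lie in [0, 1]")


def add_noise(image: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Corrupt an 8-bit image; deterministic for a fixed ``noise.seed``."""
    img = np.asarray(image)
    rng = np.random.default_rng(noise.seed)
    out = img.astype(float)
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    if noise.impulse_fraction > 0:
        hit = rng.random(out.shape) < noise.impulse_fraction
        vals = rng.choice(np.array([0.0, 255.0]), size=out.shape)
        out = np.where(hit, vals, out)
    out = np.clip(np.rint(out), 0, 255)
    return out.astype(np.uint8)


# ---------------------------------------------------------------------------
# Boundary point samples
# ---------------------------------------------------------------------------

def sample_boundary_points(model, x_range, n: int, noise_sd: float = 0.0,
                           seed: int = 0, label=None) -> BoundaryPointSet:
    """Sample (x_i, f(x_i) + eps_i) at equally spaced x over ``x_range``.

    ``n`` must be at least the parameter count of the model family (6 for
    a second-order Fourier curve).
    """
    n_par = getattr(model, "n_params", 6)
    if n < n_par:
        raise ValueError(f"need n >= {n_par} points for a {n_par}-parameter "
                         f"model, got {n}")
    x = np.linspace(float(x_range[0]), float(x_range[1]), n)
    y = np.asarray(model.value(x), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=n)
    return BoundaryPointSet(x=x, y=y, label=label)


# ---------------------------------------------------------------------------
# Indentation curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndentationProtocol:
    """Trapezoidal nanoindentation loading protocol (SI units).

    Defaults follow the standard claw-testing protocol: 3 mN peak load,
    50 µN/s loading, 50 s hold.  ``creep_rate`` adds a linear displacement
    drift during the hold (m/s, default 0).
    """

    max_load: float = 3e-3          # N
    loading_rate: float = 50e-6     # N/s
    hold_time: float = 50.0         # s
    unload_rate: float = 50e-6      # N/s
    sampling_rate: float = 10.0     # Hz
    creep_rate: float = 0.0         # m/s during hold

    def __post_init__(self) -> None:
        for name in ("max_load", "loading_rate", "unload_rate",
                     "sampling_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hold_time < 0:
            raise ValueError("hold_time must be >= 0")


#: Ideal Berkovich projected-area coefficient A_c = 24.56 h_c^2 and the
#: Oliver-Pharr constants used when constructing synthetic curves.
_AREA_COEFF = 24.56
_BETA = 1.034
_EPSILON = 0.75
_DEFAULT_M = 1.2


def generate_indentation_curve(H_true: float, Er_true: float,
                               protocol: Optional[IndentationProtocol] = None,
                               seed: int = 0,
                               noise_fraction: float = 0.0,
                               m: float = _DEFAULT_M,
                               condition: str = "dry"):
    """Synthesize a load-displacement record with known (H, E_r).

    Loading follows a Hertz-like P ∝ h² branch; unloading follows the
    power law P = B (h_d − h_f)^m, with B, h_f chosen so that Oliver-Pharr
    analysis of the noiseless curve returns ``H_true`` and ``Er_true``
    (ideal Berkovich area, β = 1.034, ε = 0.75).

    ``noise_fraction`` adds zero-mean Gaussian noise of that relative
    magnitude to the load channel; the noiseless backbone is independent
    of ``seed``.

    H_true, Er_true in Pa.  Returns an
    :class:`~clawmech.indentation.IndentationCurve`.
    """
    from .indentation import IndentationCurve  # local import, avoids a cycle

    if H_true <= 0 or Er_true <= 0:
        raise ValueError("H_true and Er_true must be positive")
    if not (1.0 <= m <= 3.0):
        raise ValueError("unloading exponent m must lie in [1, 3]")
    if protocol is None:
        protocol = IndentationProtocol()

    Pmax = protocol.max_load
    Ac = Pmax / H_true
    hc = np.sqrt(Ac / _AREA_COEFF)
    S = 2.0 * _BETA * Er_true * np.sqrt(Ac) / np.sqrt(np.pi)
    hmax = hc + _EPSILON * Pmax / S
    hf = hmax - m * Pmax / S
    if hf < 0:
        raise ValueError(
            "inconsistent (H, E_r) pair: implied final depth is negative "
            "(contact depth cannot be realised by the unloading power law)")
    B = Pmax / (hmax - hf) ** m

    dt = 1.0 / protocol.sampling_rate
    t_load = Pmax / protocol.loading_rate
    t_unload = Pmax / protocol.unload_rate

    tl = np.arange(0.0, t_load, dt)
    th = np.arange(0.0, protocol.hold_time, dt)
    tu = np.arange(0.0, t_unload + dt / 2, dt)

    P_l = protocol.loading_rate * tl
    h_l = hmax * np.sqrt(P_l / Pmax)
    P_h = np.full(th.shape, Pmax)
    h_h = hmax + protocol.creep_rate * th
    h_hold_end = hmax + protocol.creep_rate * protocol.hold_time
    P_u = np.clip(Pmax - protocol.unload_rate * tu, 0.0, None)
    h_u = hf + (P_u / B) ** (1.0 / m) + (h_hold_end - hmax)

    t = np.concatenate([tl, t_load + th, t_load + protocol.hold_time + tu])
    P = np.concatenate([P_l, P_h, P_u])
    h = np.concatenate([h_l, h_h, h_u])
    seg = np.concatenate([np.full(tl.shape, "loading", dtype=object),
                          np.full(th.shape, "hold", dtype=object),
                          np.full(tu.shape, "unloading", dtype=object)])

    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        P = P + rng.normal(0.0, noise_fraction * Pmax, size=P.shape)

    return IndentationCurve(time=t, load=P, displacement=h, segments=seg,
                            condition=condition)
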