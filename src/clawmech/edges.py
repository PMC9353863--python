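"""Multiscale B-spline wavelet modulus-maxima edge detection.

The detector is the classic Mallat-Zhong construction: an undecimated
(à-trous) dyadic wavelet transform whose smoothing filter is a cubic
B-spline binomial kernel [1, 3, 3, 1]/8 and whose detail filter is a
first-difference kernel, so the two detail fields WT¹ (along x) and WT²
(along y) approximate the gradient of the image smoothed at scale a = 2ʲ.
Edges are the local maxima of the gradient modulus

    mod = sqrt(|WT¹|² + |WT²|²)

along the gradient direction arctan2(WT², WT¹), quantized to four
orientations (0°, 45°, 90°, 135° modulo 180°), followed by a modulus
threshold λ (default 0.2 × the scale's maximum modulus).

Five classical baseline operators (Sobel, Roberts, Prewitt, LoG, Canny)
are provided for comparison; Sobel/Roberts/Prewitt are explicit
convolutions, LoG/Canny delegate to standard implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import canny as _sk_canny

__all__ = [
    "WaveletDetail",
    "EdgeMap",
    "classical_edges",
    "bspline_wavelet_decompose",
    "gradient_modulus",
    "gradient_angle",
    "quantize_direction",
    "nonmax_suppress",
    "threshold_edges",
    "multiscale_edge_detect",
]


@dataclass
class WaveletDetail:
    """Per-scale detail coefficient fields of the à-trous transform."""

    scale_index: int
    wt1: np.ndarray  # horizontal detail (derivative along x / columns)
    wt2: np.ndarray  # vertical detail (derivative along y / rows)

    def __post_init__(self) -> None:
        if self.wt1.shape != self.wt2.shape:
            raise ValueError("wt1 and wt2 must share a shape")

    @property
    def modulus(self) -> np.ndarray:
        return gradient_modulus(self)

    @property
    def angle(self) -> np.ndarray:
        return gradient_angle(self)


@dataclass
class EdgeMap:
    """Binary edge raster, optionally with the modulus it was cut from."""

    binary: np.ndarray
    modulus: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.binary = np.asarray(self.binary).astype(bool)

    @property
    def n_edge_pixels(self) -> int:
        return int(self.binary.sum())


# ---------------------------------------------------------------------------
# Classical baseline operators
# ---------------------------------------------------------------------------

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_PREWITT_X = np.array([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]], dtype=float)
_ROBERTS_A = np.array([[1, 0], [0, -1]], dtype=float)
_ROBERTS_B = np.array([[0, 1], [-1, 0]], dtype=float)


def _grad_magnitude(img, kx, ky, origin=0):
    gx = ndimage.correlate(img, kx, mode="reflect", origin=origin)
    gy = ndimage.correlate(img, ky, mode="reflect", origin=origin)
    return np.hypot(gx, gy)


def classical_edges(image: np.ndarray, operator: str,
                    threshold: Optional[float] = None,
                    rel_threshold: float = 0.2,
                    sigma: float = 2.0) -> EdgeMap:
    """Binary edge map from one of the five classical operators.

    ``threshold`` is an absolute cut on the gradient magnitude (or, for
    LoG, on the magnitude of the zero-crossing slope); when omitted it
    defaults to ``rel_threshold`` times the maximum response.  ``sigma``
    is the Gaussian scale for LoG and Canny.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    op = operator.lower()

    if op == "canny":
        binary = _sk_canny(img, sigma=sigma)
        return EdgeMap(binary=binary)

    if op == "log":
        lap = ndimage.gaussian_laplace(img, sigma=sigma)
        # zero crossings with sufficient local slope
        strength = np.maximum(
            np.abs(np.diff(lap, axis=0, prepend=lap[:1, :])),
            np.abs(np.diff(lap, axis=1, prepend=lap[:, :1])))
        sign = lap > 0
        zc = np.zeros_like(sign)
        zc[1:, :] |= sign[1:, :] != sign[:-1, :]
        zc[:, 1:] |= sign[:, 1:] != sign[:, :-1]
        cut = threshold if threshold is not None else rel_threshold * strength.max()
        return EdgeMap(binary=zc & (strength >= cut), modulus=strength)

    if op == "sobel":
        mag = _grad_magnitude(img, _SOBEL_X, _SOBEL_X.T)
    elif op == "prewitt":
        mag = _grad_magnitude(img, _PREWITT_X, _PREWITT_X.T)
    elif op == "roberts":
        mag = _grad_magnitude(img, _ROBERTS_A, _ROBERTS_B, origin=-1)
    else:
        raise ValueError(f"unknown operator {operator!r}")

    if mag.max() == 0:
        return EdgeMap(binary=np.zeros_like(mag, dtype=bool), modulus=mag)
    cut = threshold if threshold is not None else rel_threshold * mag.max()
    return EdgeMap(binary=mag >= cut, modulus=mag)


# ---------------------------------------------------------------------------
# B-spline à-trous wavelet transform
# ---------------------------------------------------------------------------

_H0 = np.array([1.0, 3.0, 3.0, 1.0]) / 8.0  # cubic B-spline smoothing
_G0 = np.array([-2.0, 2.0])                 # first-difference detail


def _dilate(filt: np.ndarray, level: int) -> np.ndarray:
    """Insert 2^level − 1 zeros between taps (à-trous dilation)."""
    if level == 0:
        return filt
    step = 2 ** level
    out = np.zeros((filt.size - 1) * step + 1)
    out[::step] = filt
    return out


def bspline_wavelet_decompose(image: np.ndarray, scale_index: int) -> WaveletDetail:
    """Detail fields WT¹, WT² of the undecimated transform at scale 2ʲ.

    The smoothing cascade uses the cubic B-spline kernel dilated à trous;
    the detail at scale j is the (dilated) first difference of the
    approximation at scale j−1, along columns (wt1) and rows (wt2).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if scale_index < 1:
        raise ValueError("scale_index must be >= 1")
    if _dilate(_H0, scale_index - 1).size > min(img.shape):
        raise ValueError("dilated filter larger than image")

    S = img
    wt1 = wt2 = None
    for level in range(scale_index):
        g = _dilate(_G0, level)
        if level == scale_index - 1:
            wt1 = ndimage.correlate1d(S, g, axis=1, mode="reflect")
            wt2 = ndimage.correlate1d(S, g, axis=0, mode="reflect")
            break
        h = _dilate(_H0, level)
        S = ndimage.correlate1d(S, h, axis=0, mode="reflect")
        S = ndimage.correlate1d(S, h, axis=1, mode="reflect")
    return WaveletDetail(scale_index=scale_index, wt1=wt1, wt2=wt2)


def gradient_modulus(detail: WaveletDetail) -> np.ndarray:
    """Elementwise Euclidean norm sqrt(wt1² + wt2²)."""
    return np.hypot(detail.wt1, detail.wt2)


def gradient_angle(detail: WaveletDetail) -> np.ndarray:
    """Full-circle gradient angle arctan2(wt2, wt1) in radians.

    Pixels where both components vanish get angle 0 (the modulus is zero
    there, so they never survive suppression anyway).
    """
    return np.arctan2(detail.wt2, detail.wt1)


def quantize_direction(angle) -> np.ndarray:
    """Quantize angles (radians) to four orientation bins modulo 180°.

    Bins: 0 → 0°/180°, 1 → 45°/225°, 2 → 90°/270°, 3 → 135°/315°.
    Exact midpoints round down to the lower-angle bin (157.5° → 135°).
    """
    deg = np.degrees(np.asarray(angle, dtype=float)) % 180.0
    idx = np.ceil(deg / 45.0 - 0.5).astype(int) % 4
    return idx


# neighbour offsets (row, col) along each quantized gradient direction
_BIN_OFFSETS = {
    0: (0, 1),    # gradient along x -> compare left/right
    1: (1, 1),    # 45°
    2: (1, 0),    # gradient along y -> compare up/down
    3: (1, -1),   # 135°
}


def nonmax_suppress(modulus: np.ndarray, bins: np.ndarray) -> np.ndarray:
    """Keep pixels that are modulus maxima along their gradient direction.

    A pixel survives iff its modulus is >= the neighbour on the negative
    side of the direction and strictly > the neighbour on the positive
    side (the asymmetric tie rule keeps plateaus from being retained
    twice — an interior run of equal values is dropped entirely).  The
    one-pixel border, which lacks a full neighbourhood, is excluded.
    """
    m = np.asarray(modulus, dtype=float)
    b = np.asarray(bins)
    if m.shape != b.shape:
        raise ValueError("modulus and bins must share a shape")
    keep = np.zeros(m.shape, dtype=bool)
    for bin_idx, (dr, dc) in _BIN_OFFSETS.items():
        prev = np.roll(m, (dr, dc), axis=(0, 1))    # neighbour at -direction
        nxt = np.roll(m, (-dr, -dc), axis=(0, 1))   # neighbour at +direction
        keep |= (b == bin_idx) & (m >= prev) & (m > nxt)
    keep[0, :] = keep[-1, :] = False
    keep[:, 0] = keep[:, -1] = False
    return np.where(keep, m, 0.0)


def threshold_edges(suppressed: np.ndarray, lam: float) -> EdgeMap:
    """Binary map of suppressed pixels whose modulus reaches λ (λ ≥ 0)."""
    if lam < 0:
        raise ValueError("threshold must be >= 0")
    s = np.asarray(suppressed, dtype=float)
    return EdgeMap(binary=(s >= lam) & (s > 0), modulus=s)


def multiscale_edge_detect(image: np.ndarray, scales: Sequence[int],
                           lam: Optional[float] = None,
                           lam_fraction: float = 0.2) -> dict:
    """Run the full modulus-maxima pipeline at each dyadic scale.

    ``lam`` is a global absolute threshold; when omitted each scale uses
    ``lam_fraction`` × its own maximum modulus.  Returns {j: EdgeMap}.
    """
    if len(scales) == 0:
        raise ValueError("scales must be non-empty")
    out = {}
    for j in scales:
        detail = bspline_wavelet_decompose(image, j)
        mod = gradient_modulus(detail)
        bins = quantize_direction(gradient_angle(detail))
        sup = nonmax_suppress(mod, bins)
        cut = lam if lam is not None else lam_fraction * float(mod.max())
        out[int(j)] = threshold_edges(sup, cut)
    return out
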