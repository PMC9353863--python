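import numpy as np
import pytest

from clawmech import NlmParams, default_phantom_spec, generate_claw_phantom


@pytest.fixture(scope="session")
def disk_image():
    """128x128 two-level image with a filled disk of radius 30 at (64, 64)."""
    from skimage.draw import disk

    img = np.full((128, 128), 60.0)
    rr, cc = disk((64, 64), 30)
    img[rr, cc] = 180.0
    return img


@pytest.fixture(scope="session")
def phantom():
    return generate_claw_phantom(default_phantom_spec())


@pytest.fixture
def small_nlm_params():
    """Parameters small enough for the literal brute-force double loop."""
    return NlmParams(patch_radius=2, search_radius=3, filter_h=20.0)


def brute_force_nlm(image, params, scheme):
    """Literal quadruple-loop NLM, the independent oracle for the fast path.

    Mirrors the documented conventions (symmetric padding, Gaussian patch
    kernel normalized to sum 1, self-weight = max of other weights) with
    scalar arithmetic only.
    """
    img = np.asarray(image, dtype=float)
    p, s = params.patch_radius, params.search_radius
    params = params.resolved(img)
    ax = np.arange(-p, p + 1)
    g = np.exp(-(ax ** 2) / (2 * params.kernel_sd ** 2))
    g = g / g.sum()
    K = np.outer(g, g)
    pad = s + p
    P = np.pad(img, pad, mode="symmetric")
    H, W = img.shape
    out = np.zeros((H, W))
    for r in range(H):
        for c in range(W):
            i0, j0 = r + pad, c + pad
            wsum = acc = wmax = 0.0
            for dy in range(-s, s + 1):
                for dx in range(-s, s + 1):
                    if dy == 0 and dx == 0:
                        continue
                    D = 0.0
                    for ky in range(-p, p + 1):
                        for kx in range(-p, p + 1):
                            d = (P[i0 + ky, j0 + kx]
                                 - P[i0 + dy + ky, j0 + dx + kx])
                            D += K[ky + p, kx + p] * d * d
                    if scheme == "original":
                        w = np.exp(-D / params.filter_h ** 2)
                    elif D <= params.filter_h2:
                        w = (np.exp(-D / params.filter_h1 ** 2)
                             * np.cos(np.pi * D / (2 * params.filter_h2)))
                    else:
                        w = 0.0
                    acc += w * P[i0 + dy, j0 + dx]
                    wsum += w
                    wmax = max(wmax, w)
            acc += wmax * P[i0, j0]
            wsum += wmax
            out[r, c] = acc / wsum if wsum > 0 else P[i0, j0]
    return np.clip(out, 0, 255)
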