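"""Boundary-curve modelling for claw silhouettes.

Extracts ordered boundary chains from binary edge maps, fits the four
candidate function families (second-order Gaussian, second-order Fourier,
second- and third-order polynomials) by least squares, scores them with
SSE/SST/R², and profiles analytic first/second derivatives and curvature

    K = |y''| / (1 + y'^2)^(3/2)

to classify concave (y'' < 0) and convex (y'' > 0) segments.

All fitting is done in micrometres; the pixel-to-µm scale is supplied by
the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FourierModel",
    "PolynomialModel",
    "Gaussian2Model",
    "BoundaryPointSet",
    "FitResult",
    "CurvatureProfile",
    "CLAW_FEATURE_CURVES",
    "extract_boundary",
    "split_x_monotone",
    "segment_curves",
    "suggest_breakpoints",
    "fit_curve",
    "goodness",
    "select_model",
    "evaluate_model",
    "curvature_profile",
]


# ---------------------------------------------------------------------------
# Closed-form curve families (value + analytic derivatives)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FourierModel:
    """Second-order Fourier series f(x) = a0 + a1 cos(xw) + b1 sin(xw)
    + a2 cos(2xw) + b2 sin(2xw).

    Amplitudes in µm, ``w`` in rad/µm.
    """

    a0: float
    a1: float
    b1: float
    a2: float
    b2: float
    w: float

    family: str = field(default="fourier2", init=False, repr=False)
    n_params: int = field(default=6, init=False, repr=False)

    def __post_init__(self) -> None:
        vals = (self.a0, self.a1, self.b1, self.a2, self.b2, self.w)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("Fourier coefficients must be finite")
        if self.w == 0:
            raise ValueError("angular frequency w must be nonzero")

    def value(self, x):
        x = np.asarray(x, dtype=float)
        t = self.w * x
        return (self.a0 + self.a1 * np.cos(t) + self.b1 * np.sin(t)
                + self.a2 * np.cos(2 * t) + self.b2 * np.sin(2 * t))

    def deriv1(self, x):
        x = np.asarray(x, dtype=float)
        t = self.w * x
        w = self.w
        return (-self.a1 * w * np.sin(t) + self.b1 * w * np.cos(t)
                - 2 * self.a2 * w * np.sin(2 * t)
                + 2 * self.b2 * w * np.cos(2 * t))

    def deriv2(self, x):
        x = np.asarray(x, dtype=float)
        t = self.w * x
        w2 = self.w ** 2
        return (-self.a1 * w2 * np.cos(t) - self.b1 * w2 * np.sin(t)
                - 4 * self.a2 * w2 * np.cos(2 * t)
                - 4 * self.b2 * w2 * np.sin(2 * t))

    __call__ = value

    def coefficients(self) -> dict:
        return {"a0": self.a0, "a1": self.a1, "b1": self.b1,
                "a2": self.a2, "b2": self.b2, "w": self.w}


@dataclass(frozen=True)
class PolynomialModel:
    """Polynomial c0 + c1 x + ... + cn x^n with coefficients in ascending order."""

    coeffs: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs", tuple(float(c) for c in self.coeffs))
        if len(self.coeffs) < 2:
            raise ValueError("need at least a linear polynomial")

    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1

    @property
    def family(self) -> str:
        return f"poly{self.degree}"

    @property
    def n_params(self) -> int:
        return len(self.coeffs)

    def value(self, x):
        return np.polynomial.polynomial.polyval(np.asarray(x, float), self.coeffs)

    def deriv1(self, x):
        d = np.polynomial.polynomial.polyder(self.coeffs, 1)
        return np.polynomial.polynomial.polyval(np.asarray(x, float), d)

    def deriv2(self, x):
        d = np.polynomial.polynomial.polyder(self.coeffs, 2)
        return np.polynomial.polynomial.polyval(np.asarray(x, float), d)

    __call__ = value

    def coefficients(self) -> dict:
        return {f"c{i}": c for i, c in enumerate(self.coeffs)}


@dataclass(frozen=True)
class Gaussian2Model:
    """Two-term Gaussian f(x) = A1 exp(-((x-c1)/s1)^2) + A2 exp(-((x-c2)/s2)^2)."""

    A1: float
    c1: float
    s1: float
    A2: float
    c2: float
    s2: float

    family: str = field(default="gaussian2", init=False, repr=False)
    n_params: int = field(default=6, init=False, repr=False)

    def __post_init__(self) -> None:
        if self.s1 <= 0 or self.s2 <= 0:
            raise ValueError("Gaussian widths must be positive")

    def _terms(self, x):
        x = np.asarray(x, dtype=float)
        u1 = (x - self.c1) / self.s1
        u2 = (x - self.c2) / self.s2
        return u1, u2, self.A1 * np.exp(-u1 ** 2), self.A2 * np.exp(-u2 ** 2)

    def value(self, x):
        _, _, t1, t2 = self._terms(x)
        return t1 + t2

    def deriv1(self, x):
        u1, u2, t1, t2 = self._terms(x)
        return -2 * u1 / self.s1 * t1 - 2 * u2 / self.s2 * t2

    def deriv2(self, x):
        u1, u2, t1, t2 = self._terms(x)
        return ((4 * u1 ** 2 - 2) / self.s1 ** 2 * t1
                + (4 * u2 ** 2 - 2) / self.s2 ** 2 * t2)

    __call__ = value

    def coefficients(self) -> dict:
        return {"A1": self.A1, "c1": self.c1, "s1": self.s1,
                "A2": self.A2, "c2": self.c2, "s2": self.s2}


#: Reference second-order Fourier fits of the four claw boundary feature
#: curves (weevil foreclaw, µm), shipped so curvature profiling can run
#: without access to raw image extractions.  Keys are segment labels 1-4.
CLAW_FEATURE_CURVES = {
    1: FourierModel(a0=-2.136e12, a1=2.847e12, b1=4.534e10,
                    a2=-7.115e11, b2=-2.267e10, w=2.09e-5),
    2: FourierModel(a0=216.4, a1=125.5, b1=-40.1,
                    a2=29.52, b2=4.189, w=0.02373),
    3: FourierModel(a0=3.167e9, a1=-2.394e9, b1=3.479e9,
                    a2=-3.773e8, b2=-9.861e8, w=-0.001086),
    4: FourierModel(a0=-1.942e13, a1=2.589e13, b1=-3.502e11,
                    a2=-6.47e12, b2=1.751e11, w=-1.774e-5),
}


# ---------------------------------------------------------------------------
# Point sets and boundary extraction
# ---------------------------------------------------------------------------

@dataclass
class BoundaryPointSet:
    """Ordered boundary points (x, y) in µm with a segment label."""

    x: np.ndarray
    y: np.ndarray
    label: object = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.x.size


_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _trace_chain(start, remaining):
    """Greedy 8-connected walk from ``start`` through ``remaining`` pixels."""
    chain = [start]
    remaining.discard(start)
    cur = start
    while True:
        nxt = None
        for dr, dc in _NBRS:
            cand = (cur[0] + dr, cur[1] + dc)
            if cand in remaining:
                nxt = cand
                break
        if nxt is None:
            break
        chain.append(nxt)
        remaining.discard(nxt)
        cur = nxt
    return chain


def extract_boundary(edges, pixel_size: float = 1.0, min_length: int = 10):
    """Trace 8-connected pixel chains in a binary edge map.

    Parameters
    ----------
    edges : array-like of bool or EdgeMap-like with ``.binary``
    pixel_size : µm per pixel used to scale (col, row) -> (x, y)
    min_length : chains with fewer pixels are dropped

    Returns a list of :class:`BoundaryPointSet`, one per chain, ordered
    along the walk.  Raises ``ValueError`` on an empty map.
    """
    binary = np.asarray(getattr(edges, "binary", edges)).astype(bool)
    if binary.ndim != 2:
        raise ValueError("edge map must be 2-D")
    pixels = set(zip(*np.nonzero(binary)))
    if not pixels:
        raise ValueError("edge map contains no edge pixels")

    def n_neighbors(p, pool):
        return sum((p[0] + dr, p[1] + dc) in pool for dr, dc in _NBRS)

    chains = []
    while pixels:
        # prefer an endpoint so open curves are traced end-to-end;
        # closed rings have none, so fall back to an arbitrary pixel
        start = None
        for p in sorted(pixels):
            if n_neighbors(p, pixels) <= 1:
                start = p
                break
        if start is None:
            start = min(pixels)
        chain = _trace_chain(start, pixels)
        if len(chain) >= min_length:
            # closed ring: rotate so the walk starts at the leftmost pixel,
            # which makes the x-monotone split yield two clean arcs
            first, last = chain[0], chain[-1]
            if max(abs(first[0] - last[0]), abs(first[1] - last[1])) <= 1:
                k = min(range(len(chain)), key=lambda i: chain[i][::-1])
                chain = chain[k:] + chain[:k]
            chains.append(chain)

    out = []
    for i, chain in enumerate(chains):
        rows = np.array([p[0] for p in chain], dtype=float)
        cols = np.array([p[1] for p in chain], dtype=float)
        out.append(BoundaryPointSet(x=cols * pixel_size, y=rows * pixel_size,
                                    label=i))
    return out


def split_x_monotone(points: BoundaryPointSet, min_length: int = 3):
    """Split an ordered chain into maximal strictly x-monotone runs."""
    x = points.x
    if x.size < 2:
        return [points]
    d = np.sign(np.diff(x))
    segments = []
    start = 0
    cur_sign = 0
    for i, s in enumerate(d):
        if s == 0:
            # repeated x cannot stay in a strictly monotone run
            segments.append((start, i + 1))
            start = i + 1
            cur_sign = 0
        elif cur_sign == 0:
            cur_sign = s
        elif s != cur_sign:
            segments.append((start, i + 1))
            start = i + 1
            cur_sign = 0
    segments.append((start, x.size))

    out = []
    for a, b in segments:
        if b - a >= min_length:
            xs, ys = points.x[a:b], points.y[a:b]
            if xs[0] > xs[-1]:
                xs, ys = xs[::-1], ys[::-1]
            out.append(BoundaryPointSet(xs, ys, label=points.label))
    return out


def segment_curves(points: BoundaryPointSet, breakpoints: Sequence[float]):
    """Split an x-monotone point set into four labelled feature segments.

    ``breakpoints`` are three x positions strictly inside the data range,
    in increasing order.  A point whose x equals a breakpoint goes to the
    left segment.
    """
    bp = [float(b) for b in breakpoints]
    if len(bp) != 3:
        raise ValueError("exactly 3 breakpoints required")
    if sorted(bp) != bp or len(set(bp)) != 3:
        raise ValueError("breakpoints must be strictly increasing")
    x = points.x
    lo, hi = x.min(), x.max()
    if bp[0] <= lo or bp[-1] >= hi:
        raise ValueError("breakpoints must lie strictly inside the x-range")

    edges_ = [-np.inf] + bp + [np.inf]
    out = []
    for k in range(4):
        mask = (x > edges_[k]) & (x <= edges_[k + 1])
        out.append(BoundaryPointSet(x[mask], points.y[mask], label=k + 1))
    return out


def suggest_breakpoints(points: BoundaryPointSet, n_breaks: int = 3):
    """Suggest segment breakpoints at inflections of a smooth global fit.

    A polynomial of degree ``n_breaks + 2`` is fitted to the points; the
    real roots of its second derivative inside the data range are the
    candidate breakpoints (up to ``n_breaks``, ordered by x).
    """
    x, y = points.x, points.y
    if x.size < n_breaks + 3:
        raise ValueError("too few points to suggest breakpoints")
    # fit on a shifted/scaled abscissa for conditioning
    x0, sc = x.mean(), max(x.std(), 1e-12)
    t = (x - x0) / sc
    coeffs = np.polynomial.polynomial.polyfit(t, y, deg=n_breaks + 2)
    d2 = np.polynomial.polynomial.polyder(coeffs, 2)
    roots = np.polynomial.polynomial.polyroots(d2)
    roots = roots[np.abs(roots.imag) < 1e-8].real
    xr = roots * sc + x0
    xr = np.sort(xr[(xr > x.min()) & (xr < x.max())])
    return list(xr[:n_breaks])


# ---------------------------------------------------------------------------
# Least-squares fitting and goodness of fit
# ---------------------------------------------------------------------------

def goodness(y, yhat):
    """Return (SSE, SST, R²) with SSE = Σ(y−ŷ)², SST = Σ(y−ȳ)²,
    R² = 1 − SSE/SST.  Raises on SST = 0 (constant data)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same length")
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("SST is zero (constant data): R² undefined")
    return sse, sst, 1.0 - sse / sst


@dataclass
class FitResult:
    """Outcome of fitting one function family to one boundary segment.

    ``stderr`` maps coefficient names to asymptotic standard errors from
    the Gauss-Newton covariance s² (JᵀJ)⁻¹ at the optimum.
    """

    family: str
    model: object
    sse: float
    sst: float
    r_squared: float
    yhat: np.ndarray
    x_range: tuple
    n_points: int
    success: bool = True
    message: str = ""
    stderr: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return self.model.n_params if self.model is not None else 0

    def coefficients(self) -> dict:
        return self.model.coefficients() if self.model is not None else {}


_FAMILIES = ("gaussian2", "fourier2", "poly2", "poly3")


def _fourier_design(x, w):
    t = w * x
    return np.column_stack([np.ones_like(x), np.cos(t), np.sin(t),
                            np.cos(2 * t), np.sin(2 * t)])


def _init_fourier_w(x, y):
    """Seed w from the dominant discrete-Fourier peak of the detrended data."""
    n = x.size
    # detrend (remove linear component) so the fundamental dominates
    A = np.column_stack([np.ones(n), x])
    resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    dx = (x[-1] - x[0]) / max(n - 1, 1)
    spec = np.abs(np.fft.rfft(resid))
    freqs = np.fft.rfftfreq(n, d=dx)
    if spec.size > 1:
        kpk = 1 + int(np.argmax(spec[1:]))
        w0 = 2 * np.pi * freqs[kpk]
    else:
        w0 = 0.0
    span = x[-1] - x[0]
    w_min = np.pi / (2 * span) if span > 0 else 1e-3
    return max(w0, w_min), w_min


def _fit_fourier2(x, y):
    w0, w_min = _init_fourier_w(x, y)
    best = None
    for w_try in (w0, 0.5 * w0, 2.0 * w0, w_min):
        if w_try <= 0:
            continue
        amps, res, _, _ = np.linalg.lstsq(_fourier_design(x, w_try), y,
                                          rcond=None)
        p0 = [amps[0], amps[1], amps[2], amps[3], amps[4], w_try]

        def f(xx, a0, a1, b1, a2, b2, w):
            t = w * xx
            return (a0 + a1 * np.cos(t) + b1 * np.sin(t)
                    + a2 * np.cos(2 * t) + b2 * np.sin(2 * t))

        try:
            popt, _ = curve_fit(f, x, y, p0=p0, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        if popt[5] == 0:
            continue
        # canonical sign: f(x; -w, b -> -b) is the same curve, so report w > 0
        if popt[5] < 0:
            popt = [popt[0], popt[1], -popt[2], popt[3], -popt[4], -popt[5]]
        model = FourierModel(*popt)
        sse = float(np.sum((y - model.value(x)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, model)
    if best is None:
        raise RuntimeError("fourier2 fit did not converge from any seed")
    return best[1]


def _fit_gaussian2(x, y):
    # seed centres at the two largest local maxima of lightly smoothed data
    ys = np.convolve(y, np.ones(5) / 5, mode="same") if y.size >= 5 else y
    interior = np.arange(1, x.size - 1)
    is_max = (ys[interior] >= ys[interior - 1]) & (ys[interior] >= ys[interior + 1])
    cand = interior[is_max]
    if cand.size >= 2:
        top2 = cand[np.argsort(ys[cand])[::-1][:2]]
    else:
        top2 = np.array([x.size // 4, 3 * x.size // 4])
    span = max(x[-1] - x[0], 1e-9)
    p0 = [ys[top2[0]], x[top2[0]], span / 6,
          ys[top2[1]], x[top2[1]], span / 6]

    def f(xx, A1, c1, s1, A2, c2, s2):
        return (A1 * np.exp(-((xx - c1) / s1) ** 2)
                + A2 * np.exp(-((xx - c2) / s2) ** 2))

    lb = [-np.inf, -np.inf, 1e-12, -np.inf, -np.inf, 1e-12]
    ub = [np.inf] * 6
    popt, _ = curve_fit(f, x, y, p0=p0, bounds=(lb, ub), maxfev=20000)
    return Gaussian2Model(*popt)


def fit_curve(points: BoundaryPointSet, family: str) -> FitResult:
    """Least-squares fit of one function family to an x-monotone segment.

    Nonlinear families (fourier2, gaussian2) are seeded from the data
    (dominant spectral peak / two largest local maxima); a failure to
    converge is reported in the result, never raised silently.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {_FAMILIES}")
    x, y = points.x, points.y
    n_par = {"gaussian2": 6, "fourier2": 6, "poly2": 3, "poly3": 4}[family]
    if x.size < n_par:
        raise ValueError(f"{family} needs at least {n_par} points, got {x.size}")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing within a segment")

    try:
        if family in ("poly2", "poly3"):
            deg = int(family[-1])
            coeffs = np.polynomial.polynomial.polyfit(x, y, deg)
            model = PolynomialModel(tuple(coeffs))
        elif family == "fourier2":
            model = _fit_fourier2(x, y)
        else:
            model = _fit_gaussian2(x, y)
    except (RuntimeError, ValueError) as exc:
        return FitResult(family=family, model=None, sse=np.nan, sst=np.nan,
                         r_squared=np.nan, yhat=np.full_like(x, np.nan),
                         x_range=(float(x.min()), float(x.max())),
                         n_points=x.size, success=False, message=str(exc))

    yhat = model.value(x)
    sse, sst, r2 = goodness(y, yhat)
    return FitResult(family=family, model=model, sse=sse, sst=sst,
                     r_squared=r2, yhat=yhat,
                     x_range=(float(x.min()), float(x.max())),
                     n_points=x.size,
                     stderr=_coefficient_stderr(model, x, sse))


def _rebuild(model, coeffs: dict):
    if isinstance(model, PolynomialModel):
        return PolynomialModel(tuple(coeffs[f"c{i}"]
                                     for i in range(model.n_params)))
    return type(model)(**coeffs)


def _coefficient_stderr(model, x, sse) -> dict:
    """Asymptotic standard errors via a finite-difference Jacobian."""
    names = list(model.coefficients())
    base = model.coefficients()
    y0 = model.value(x)
    n, p = x.size, len(names)
    if n <= p:
        return {k: np.nan for k in names}
    J = np.empty((n, p))
    for k, name in enumerate(names):
        eps = 1e-6 * max(abs(base[name]), 1e-9)
        pert = dict(base)
        pert[name] = base[name] + eps
        try:
            J[:, k] = (_rebuild(model, pert).value(x) - y0) / eps
        except ValueError:
            J[:, k] = 0.0
    s2 = sse / (n - p)
    cov = s2 * np.linalg.pinv(J.T @ J)
    return {name: float(np.sqrt(max(cov[k, k], 0.0)))
            for k, name in enumerate(names)}


def select_model(fits: Sequence[FitResult]) -> FitResult:
    """Pick the successful fit with maximal R²; ties go to fewer parameters."""
    ok = [f for f in fits if f.success]
    if not ok:
        raise ValueError("all fits failed; nothing to select")
    return max(ok, key=lambda f: (f.r_squared, -f.n_params))


def evaluate_model(model, x):
    """Evaluate a closed-form model: returns (y, y', y'') analytically."""
    return model.value(x), model.deriv1(x), model.deriv2(x)


# ---------------------------------------------------------------------------
# Curvature
# ---------------------------------------------------------------------------

@dataclass
class CurvatureProfile:
    """Curvature K = |y''| / (1+y'^2)^{3/2} along a fitted segment."""

    x: np.ndarray
    y: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    K: np.ndarray
    max_K: float
    x_at_max_K: float
    classification: str  # 'concave', 'convex' or 'mixed'


def curvature_profile(model, x_range, n_grid: int = 500) -> CurvatureProfile:
    """Profile curvature of a fitted model over ``x_range`` (analytic
    derivatives; no numerical differentiation).

    The segment is classified 'concave' if y'' < 0 on the whole grid,
    'convex' if y'' > 0, else 'mixed'.
    """
    lo, hi = float(x_range[0]), float(x_range[1])
    if not (hi > lo) or n_grid < 2:
        raise ValueError("need x_range[1] > x_range[0] and n_grid >= 2")
    x = np.linspace(lo, hi, n_grid)
    y, y1, y2 = evaluate_model(model, x)
    K = np.abs(y2) / (1.0 + y1 ** 2) ** 1.5
    imax = int(np.argmax(K))
    if np.all(y2 < 0):
        cls = "concave"
    elif np.all(y2 > 0):
        cls = "convex"
    else:
        cls = "mixed"
    return CurvatureProfile(x=x, y=y, y1=y1, y2=y2, K=K,
                            max_K=float(K[imax]), x_at_max_K=float(x[imax]),
                            classification=cls)
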