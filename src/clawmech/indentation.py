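"""Oliver-Pharr analysis of nanoindentation load-displacement curves.

From the unloading branch of a load-displacement record the method
extracts the contact stiffness S (slope of the power-law fit
P = B (h_d − h_f)^m at the onset of unloading), the contact depth
h_c = h_max − ε P_max / S, the projected contact area A_c (ideal
Berkovich, 24.56 h_c², optional first-order tip-rounding correction),
and from these

    H   = P_max / A_c
    E_r = sqrt(π) · S / (2 β sqrt(A_c))
    E   = (1 − ν²) / (1/E_r − (1 − ν_i²)/E_i)

with β = 1.034 and ε = 0.75 (standard Berkovich / power-law values) and a
diamond indenter (E_i = 1140 GPa, ν_i = 0.07) by default.  All quantities
are SI internally; summary tables report GPa.

The reported "modulus" of cuticle specimens is ambiguous between E_r and
the specimen-side E, so results carry both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "IndentationCurve",
    "IndentationConfig",
    "IndentationResult",
    "split_segments",
    "fit_unloading",
    "contact_area",
    "hardness",
    "reduced_modulus",
    "specimen_modulus",
    "analyze_curve",
    "summarize",
    "dry_wet_ratio",
]

_GPA = 1e9


@dataclass
class IndentationCurve:
    """Load-displacement record (SI units) with segment labels."""

    time: np.ndarray          # s
    load: np.ndarray          # N
    displacement: np.ndarray  # m
    segments: Optional[np.ndarray] = None  # 'loading' | 'hold' | 'unloading'
    condition: str = "dry"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        n = self.time.size
        if self.load.size != n or self.displacement.size != n:
            raise ValueError("time, load and displacement must align")
        if self.segments is None:
            self.segments = split_segments(self.load)
        else:
            self.segments = np.asarray(self.segments, dtype=object)
            if self.segments.size != n:
                raise ValueError("segment labels must align with samples")

    def segment(self, name: str) -> "IndentationCurve":
        mask = self.segments == name
        return IndentationCurve(self.time[mask], self.load[mask],
                                self.displacement[mask],
                                self.segments[mask], self.condition)


def split_segments(load: np.ndarray, tol_fraction: float = 0.002) -> np.ndarray:
    """Label samples loading/hold/unloading from the load history alone.

    The hold is the contiguous run around the load maximum where the load
    stays within ``tol_fraction`` of the peak.
    """
    P = np.asarray(load, dtype=float)
    if P.size < 3:
        raise ValueError("record too short to segment")
    pmax = P.max()
    near = P >= pmax * (1 - tol_fraction)
    ipk = int(np.argmax(P))
    lo = ipk
    while lo > 0 and near[lo - 1]:
        lo -= 1
    hi = ipk
    while hi < P.size - 1 and near[hi + 1]:
        hi += 1
    seg = np.empty(P.size, dtype=object)
    seg[:lo] = "loading"
    seg[lo:hi + 1] = "hold"
    seg[hi + 1:] = "unloading"
    return seg


@dataclass(frozen=True)
class IndentationConfig:
    """Oliver-Pharr analysis constants (SI units)."""

    beta: float = 1.034            # indenter geometry constant
    epsilon: float = 0.75          # contact-depth intercept factor
    area_coefficient: float = 24.56
    tip_radius: float = 200e-9     # m
    tip_correction: bool = False   # first-order blunt-tip area term
    indenter_modulus: float = 1140e9   # Pa (diamond)
    indenter_poisson: float = 0.07
    specimen_poisson: float = 0.3
    unload_fit_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.epsilon <= 0:
            raise ValueError("beta and epsilon must be positive")
        for name in ("indenter_poisson", "specimen_poisson"):
            if not (0 < getattr(self, name) < 0.5):
                raise ValueError(f"{name} must lie in (0, 0.5)")
        if not (0 < self.unload_fit_fraction <= 1):
            raise ValueError("unload_fit_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class IndentationResult:
    """Derived mechanical quantities for one indentation curve."""

    S: float              # N/m
    h_max: float          # m
    h_final: float        # m
    h_contact: float      # m
    exponent_m: float
    P_max: float          # N
    A_c: float            # m^2
    H: float              # Pa
    E_r: float            # Pa
    E: float              # Pa
    condition: str = "dry"


def fit_unloading(curve: IndentationCurve,
                  config: Optional[IndentationConfig] = None):
    """Fit P = B (h_d − h_f)^m to the top of the unloading branch.

    Uses the ``unload_fit_fraction`` of unloading samples closest to peak
    displacement.  Returns (S, h_f, m, B) where S = dP/dh_d evaluated at
    the maximum displacement.  Raises ``ValueError`` on an invalid
    segment; non-physical fits (m outside [1, 3]) are rejected.
    """
    config = config or IndentationConfig()
    unl = curve.segment("unloading")
    h, P = unl.displacement, unl.load
    if h.size < 10:
        raise ValueError("unloading segment needs at least 10 samples")
    dP = np.diff(P)
    if np.all(dP >= 0):
        raise ValueError("segment labelled 'unloading' has increasing load")

    order = np.argsort(h)[::-1]          # from peak displacement downwards
    n_fit = max(10, int(round(config.unload_fit_fraction * h.size)))
    idx = order[:n_fit]
    hmax = float(h.max())
    h_end = float(h[np.argmin(P)])

    # fit in dimensionless units (h/hmax, P/Pmax) so the three parameters
    # share a common magnitude; B would otherwise dwarf hf by ~10 orders
    h_scale = max(hmax, 1e-12)
    P_scale = float(P[idx].max())
    hn, Pn = h[idx] / h_scale, P[idx] / P_scale
    hf_hi = hn.min() * (1 - 1e-9)

    def f(hh, b, hfn, m):
        return b * np.clip(hh - hfn, 0.0, None) ** m

    p0 = [1.0, min(0.99 * h_end / h_scale, hf_hi - 1e-6), 1.5]
    try:
        popt, _ = curve_fit(f, hn, Pn, p0=p0,
                            bounds=([0, -np.inf, 0.8],
                                    [np.inf, hf_hi, 3.5]),
                            maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unloading fit did not converge: {exc}") from exc
    b, hfn, m = popt
    if not (1.0 <= m <= 3.0):
        raise ValueError(f"unloading exponent m = {m:.3f} outside [1, 3]")
    hf = hfn * h_scale
    B = b * P_scale / h_scale ** m
    S = m * B * (hmax - hf) ** (m - 1.0)
    return float(S), float(hf), float(m), float(B)


def contact_area(h_max: float, P_max: float, S: float,
                 config: Optional[IndentationConfig] = None) -> float:
    """Projected contact area from h_c = h_max − ε P_max / S.

    Ideal Berkovich area 24.56 h_c²; with ``tip_correction`` a first-order
    blunt-tip term 2 π R_tip h_c is added.  Raises if the implied contact
    depth is non-positive.
    """
    config = config or IndentationConfig()
    if S <= 0:
        raise ValueError("stiffness must be positive")
    h_c = h_max - config.epsilon * P_max / S
    if h_c <= 0:
        raise ValueError("non-positive contact depth: inconsistent "
                         "h_max, P_max, S combination")
    A = config.area_coefficient * h_c ** 2
    if config.tip_correction:
        A += 2.0 * math.pi * config.tip_radius * h_c
    return float(A)


def hardness(P_max: float, A_c: float) -> float:
    """Indentation hardness H = P_max / A_c (Pa for SI inputs)."""
    if A_c <= 0:
        raise ValueError("contact area must be positive")
    return P_max / A_c


def reduced_modulus(S: float, A_c: float, beta: float = 1.034) -> float:
    """Reduced modulus E_r = sqrt(π) S / (2 β sqrt(A_c))."""
    if S <= 0 or A_c <= 0:
        raise ValueError("S and A_c must be positive")
    return math.sqrt(math.pi) * S / (2.0 * beta * math.sqrt(A_c))


def specimen_modulus(E_r: float, nu: float, nu_i: float, E_i: float) -> float:
    """Specimen Young's modulus from 1/E_r = (1−ν²)/E + (1−ν_i²)/E_i."""
    if E_r <= 0 or E_i <= 0:
        raise ValueError("moduli must be positive")
    inv = 1.0 / E_r - (1.0 - nu_i ** 2) / E_i
    if inv <= 0:
        raise ValueError("E_r too large for this indenter: specimen "
                         "compliance would be non-positive")
    return (1.0 - nu ** 2) / inv


def analyze_curve(curve: IndentationCurve,
                  config: Optional[IndentationConfig] = None) -> IndentationResult:
    """Full Oliver-Pharr pipeline for one curve."""
    config = config or IndentationConfig()
    S, hf, m, _B = fit_unloading(curve, config)
    unl = curve.segment("unloading")
    h_max = float(unl.displacement.max())
    # mean over the hold plateau is robust to per-sample load noise,
    # unlike the max over the whole record
    hold = curve.load[curve.segments == "hold"]
    P_max = float(hold.mean()) if hold.size else float(curve.load.max())
    A_c = contact_area(h_max, P_max, S, config)
    H = hardness(P_max, A_c)
    E_r = reduced_modulus(S, A_c, config.beta)
    E = specimen_modulus(E_r, config.specimen_poisson,
                         config.indenter_poisson, config.indenter_modulus)
    return IndentationResult(S=S, h_max=h_max, h_final=hf,
                             h_contact=h_max - config.epsilon * P_max / S,
                             exponent_m=m, P_max=P_max, A_c=A_c,
                             H=H, E_r=E_r, E=E, condition=curve.condition)


def dry_wet_ratio(dry_mean: float, wet_mean: float, ndigits: int = 2) -> float:
    """Ratio of condition means, rounded to ``ndigits`` decimals."""
    if wet_mean == 0:
        raise ValueError("wet mean is zero")
    return round(dry_mean / wet_mean, ndigits)


def summarize(results: Sequence[IndentationResult],
              min_per_group: int = 2) -> dict:
    """Per-condition mean ± SD of H, E_r and E (GPa) plus dry/wet ratios.

    Returns {'table': DataFrame indexed by condition, 'ratios': dict}.
    SDs are sample standard deviations (ddof 1).  Ratios of means are
    rounded to 2 decimals and reported when both conditions are present.
    """
    if not results:
        raise ValueError("no results to summarize")
    df = pd.DataFrame([{"condition": r.condition, "H_GPa": r.H / _GPA,
                        "Er_GPa": r.E_r / _GPA, "E_GPa": r.E / _GPA}
                       for r in results])
    counts = df.groupby("condition").size()
    if (counts < min_per_group).any():
        bad = counts[counts < min_per_group].index.tolist()
        raise ValueError(f"conditions {bad} have fewer than "
                         f"{min_per_group} results")
    table = df.groupby("condition").agg(["mean", "std", "count"])
    ratios = {}
    if {"dry", "wet"} <= set(counts.index):
        means = df.groupby("condition").mean()
        for col, name in (("H_GPa", "hardness"), ("Er_GPa", "reduced_modulus"),
                          ("E_GPa", "modulus")):
            ratios[name] = dry_wet_ratio(means.loc["dry", col],
                                         means.loc["wet", col])
    return {"table": table, "ratios": ratios}
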