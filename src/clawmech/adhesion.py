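"""Claw-tip / particle adhesion mechanics (rigid-body statics).

The claw tip is idealised as a circle of radius r grasping spherical
surface asperities of radius R.  Two regimes follow from the particle
spacing d:

* single contact, d > 2(R+r):  the pressure angle follows from the embed
  depth h via sin α = (r+h)/(r+R); the grasp self-locks iff α < arctan μ,
  equivalently the load angle θ = arctan μ − α is positive.
* double contact, d ≤ 2(R+r):  α = arccos(d / (2(R+r))) from the law of
  cosines; the driving force F at load angle θ is shared between a lower
  (N1) and an upper (N2) contact.

For the two-contact case the horizontal/vertical equilibrium

    Fp = F sin θ = (N1 − N2)(μ cos α − sin α)
    Fv = F cos θ = (N1 + N2)(μ sin α + cos α)

is solved as a linear system in (N1, N2); the printed closed-form chain
for k = N1/N2 is retained as an independent cross-check.  The limit load
angle, where N1 = 0 and the upper particle becomes the sole support, is
θ_limit = arctan((tan α − μ)/(1 + μ tan α)).

Angles are radians internally; sweep tables report degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "AdhesionGeometry",
    "ForceBalance",
    "load_angle",
    "pressure_angle_single",
    "pressure_angle_double",
    "can_attach",
    "force_distribution",
    "k_closed_form",
    "limit_load_angle",
    "sweep",
]


@dataclass(frozen=True)
class AdhesionGeometry:
    """Claw-tip contact geometry and loading (SI units, radians)."""

    tip_radius: float              # r
    particle_radius: float         # R
    particle_spacing: float        # d
    embed_depth: float = 0.0       # h, single-contact regime
    friction_coefficient: float = 0.5
    load_angle: float = 0.0        # θ
    driving_force: float = 3.0     # F, N

    def __post_init__(self) -> None:
        if self.tip_radius <= 0 or self.particle_radius <= 0:
            raise ValueError("tip and particle radii must be positive")
        if not (0 <= self.embed_depth <= self.particle_radius):
            raise ValueError("embed depth must satisfy 0 <= h <= R")
        if self.friction_coefficient < 0:
            raise ValueError("friction coefficient must be >= 0")
        if self.particle_spacing <= 0:
            raise ValueError("particle spacing must be positive")

    @property
    def single_contact(self) -> bool:
        return self.particle_spacing > 2 * (self.particle_radius
                                            + self.tip_radius)

    def pressure_angle(self) -> float:
        if self.single_contact:
            return pressure_angle_single(self.tip_radius,
                                         self.particle_radius,
                                         self.embed_depth)
        return pressure_angle_double(self.tip_radius, self.particle_radius,
                                     self.particle_spacing)


def load_angle(alpha: float, mu: float) -> float:
    """Self-locking load angle θ = arctan μ − α (radians).

    θ > 0 means friction can sustain the grasp; θ ≤ 0 means the claw
    cannot self-lock and releases.  This form is regular everywhere the
    singular tan θ = (μ − tan α)/(μ tan α − 1) expression is not.
    """
    if mu < 0:
        raise ValueError("friction coefficient must be >= 0")
    if not (0 <= alpha < math.pi / 2):
        raise ValueError("pressure angle must lie in [0, pi/2)")
    return math.atan(mu) - alpha


def pressure_angle_single(r: float, R: float, h: float) -> float:
    """Single-contact pressure angle from sin α = (r+h)/(r+R).

    At the limit embed depth h = R this returns π/2: the tip geometry no
    longer meets the adhesion condition.
    """
    if r <= 0 or R <= 0:
        raise ValueError("radii must be positive")
    if not (0 <= h <= R):
        raise ValueError("embed depth must satisfy 0 <= h <= R")
    ratio = (r + h) / (r + R)
    if ratio > 1:
        raise ValueError("impossible geometry: (r+h)/(r+R) > 1")
    return math.asin(ratio)


def pressure_angle_double(r: float, R: float, d: float) -> float:
    """Two-contact pressure angle α = arccos(d / (2(R+r)))."""
    if r <= 0 or R <= 0:
        raise ValueError("radii must be positive")
    if d <= 0:
        raise ValueError("particle spacing must be positive")
    ratio = d / (2.0 * (R + r))
    if ratio > 1:
        raise ValueError("d > 2(R+r): particles too far apart for the "
                         "two-contact regime (use the single-contact model)")
    return math.acos(ratio)


def can_attach(geometry: AdhesionGeometry) -> bool:
    """True iff the regime-appropriate pressure angle satisfies
    α < arctan μ (equivalently, the load angle is strictly positive);
    the boundary α = arctan μ cannot self-lock and reports False."""
    alpha = geometry.pressure_angle()
    return load_angle(alpha, geometry.friction_coefficient) > 0


@dataclass(frozen=True)
class ForceBalance:
    """Resolved two-contact force system at one (F, θ, α, μ) operating point."""

    F: float
    theta: float
    alpha: float
    mu: float
    N1: float
    N2: float
    Ff1: float
    Ff2: float
    Fp: float
    Fv: float
    Fp1: float
    Fv1: float
    Fp2: float
    Fv2: float
    k: float            # N1/N2 (inf when N2 = 0)
    beyond_limit: bool  # N1 has reversed sign (θ past the limit angle)

    def residuals(self) -> np.ndarray:
        """Residuals of the six equilibrium relations (should be ~0)."""
        return np.array([
            self.Fp - self.F * math.sin(self.theta),
            self.Fv - self.F * math.cos(self.theta),
            self.Ff1 * math.cos(self.alpha)
            - (self.N1 * math.sin(self.alpha) + self.Fp1),
            self.Ff1 * math.sin(self.alpha) + self.N1 * math.cos(self.alpha)
            - self.Fv1,
            self.Ff2 * math.cos(self.alpha)
            - (self.N2 * math.sin(self.alpha) + self.Fp2),
            self.Ff2 * math.sin(self.alpha) + self.N2 * math.cos(self.alpha)
            - self.Fv2,
        ])


def force_distribution(F: float, theta: float, alpha: float,
                       mu: float) -> ForceBalance:
    """Solve the two-contact equilibrium for (N1, N2) at load angle θ.

    The horizontal component Fp = F sin θ is carried by the *difference*
    of the two contact reactions and the vertical component Fv = F cos θ
    by their sum.  Past the limit angle N1 is reported with its reversed
    sign and ``beyond_limit`` set, rather than clamped.

    Raises ``ValueError`` on the friction-cone boundary μ cos α = sin α,
    where the horizontal equation is singular.
    """
    if F < 0:
        raise ValueError("driving force must be >= 0")
    if mu < 0:
        raise ValueError("friction coefficient must be >= 0")
    cp = mu * math.cos(alpha) - math.sin(alpha)
    cv = mu * math.sin(alpha) + math.cos(alpha)
    if abs(cp) < 1e-12 * max(1.0, mu):
        raise ValueError("singular configuration: mu*cos(alpha) = sin(alpha) "
                         "(friction-cone boundary)")
    Fp = F * math.sin(theta)
    Fv = F * math.cos(theta)
    diff = Fp / cp            # N1 - N2
    tot = Fv / cv             # N1 + N2
    N1 = 0.5 * (tot + diff)
    N2 = 0.5 * (tot - diff)
    k = N1 / N2 if N2 != 0 else math.inf * (1 if N1 >= 0 else -1)
    Ff1, Ff2 = mu * N1, mu * N2
    return ForceBalance(
        F=F, theta=theta, alpha=alpha, mu=mu, N1=N1, N2=N2,
        Ff1=Ff1, Ff2=Ff2, Fp=Fp, Fv=Fv,
        Fp1=Ff1 * math.cos(alpha) - N1 * math.sin(alpha),
        Fv1=Ff1 * math.sin(alpha) + N1 * math.cos(alpha),
        Fp2=Ff2 * math.cos(alpha) - N2 * math.sin(alpha),
        Fv2=Ff2 * math.sin(alpha) + N2 * math.cos(alpha),
        k=k, beyond_limit=N1 < 0)


def k_closed_form(theta: float, alpha: float, mu: float) -> float:
    """Printed closed form for k = N1/N2 (independent cross-check):

    k = (tanα − μ − μ tanα tanθ − tanθ) / (tanα − μ + μ tanα tanθ + tanθ)
    """
    ta, tt = math.tan(alpha), math.tan(theta)
    num = ta - mu - mu * ta * tt - tt
    den = ta - mu + mu * ta * tt + tt
    return num / den


def limit_load_angle(alpha: float, mu: float) -> float:
    """Load angle at which N1 vanishes: arctan((tanα − μ)/(1 + μ tanα)).

    Defined only for tan α > μ (otherwise N1 stays positive for all
    θ ≥ 0 and there is no positive root).
    """
    if mu < 0:
        raise ValueError("friction coefficient must be >= 0")
    if not (0 <= alpha < math.pi / 2):
        raise ValueError("pressure angle must lie in [0, pi/2)")
    ta = math.tan(alpha)
    if ta <= mu:
        raise ValueError("tan(alpha) <= mu: N1 never crosses zero for "
                         "theta in (0, 90 deg)")
    return math.atan((ta - mu) / (1.0 + mu * ta))


# ---------------------------------------------------------------------------
# Sweep tables
# ---------------------------------------------------------------------------

_RELATIONSHIPS = ("theta_vs_alpha_mu", "alpha_vs_R_over_r",
                  "alpha_vs_d_R_r", "forces_vs_theta")


def sweep(relationship: str, grid: dict,
          fixed: Optional[dict] = None) -> pd.DataFrame:
    """Tabulate one of the model relationships over a parameter grid.

    relationship:
      * ``theta_vs_alpha_mu``: θ(α, μ); grid keys ``alpha_deg``, ``mu``.
      * ``alpha_vs_R_over_r``: α(R/r, h/R) single-contact; grid keys
        ``R_over_r``, ``h_over_R``.
      * ``alpha_vs_d_R_r``: α(d) two-contact; grid keys ``d``, fixed keys
        ``r``, ``R``.
      * ``forces_vs_theta``: (N1, N2, Fp, Fv, k)(θ); grid key
        ``theta_deg``; fixed keys ``alpha_deg``, ``mu``, ``F``
        (defaults 45°, 0.5, 3 N — the worked quantitative case).

    Singular grid points are flagged per-row (``singular`` column, NaN
    values), not fatal.
    """
    fixed = dict(fixed or {})
    if relationship not in _RELATIONSHIPS:
        raise ValueError(f"unknown relationship {relationship!r}")

    rows = []
    if relationship == "theta_vs_alpha_mu":
        alphas = np.atleast_1d(grid["alpha_deg"])
        mus = np.atleast_1d(grid["mu"])
        if alphas.size == 0 or mus.size == 0:
            raise ValueError("empty grid")
        for mu in mus:
            for a in alphas:
                th = load_angle(math.radians(a), mu)
                rows.append({"alpha_deg": a, "mu": mu,
                             "theta_deg": math.degrees(th)})
    elif relationship == "alpha_vs_R_over_r":
        ratios = np.atleast_1d(grid["R_over_r"])
        hr = np.atleast_1d(grid.get("h_over_R", [0.0]))
        if ratios.size == 0:
            raise ValueError("empty grid")
        for q in hr:
            for rr in ratios:
                a = pressure_angle_single(1.0, rr, q * rr)
                rows.append({"R_over_r": rr, "h_over_R": q,
                             "alpha_deg": math.degrees(a)})
    elif relationship == "alpha_vs_d_R_r":
        ds = np.atleast_1d(grid["d"])
        if ds.size == 0:
            raise ValueError("empty grid")
        r, R = fixed.get("r", 1.0), fixed.get("R", 10.0)
        for d in ds:
            try:
                a = math.degrees(pressure_angle_double(r, R, d))
                rows.append({"d": d, "r": r, "R": R, "alpha_deg": a,
                             "singular": False})
            except ValueError:
                rows.append({"d": d, "r": r, "R": R, "alpha_deg": np.nan,
                             "singular": True})
    else:  # forces_vs_theta
        thetas = np.atleast_1d(grid["theta_deg"])
        if thetas.size == 0:
            raise ValueError("empty grid")
        a = math.radians(fixed.get("alpha_deg", 45.0))
        mu = fixed.get("mu", 0.5)
        F = fixed.get("F", 3.0)
        for td in thetas:
            try:
                fb = force_distribution(F, math.radians(td), a, mu)
                rows.append({"theta_deg": td, "N1_N": fb.N1, "N2_N": fb.N2,
                             "Fp_N": fb.Fp, "Fv_N": fb.Fv, "k": fb.k,
                             "beyond_limit": fb.beyond_limit,
                             "singular": False})
            except ValueError:
                rows.append({"theta_deg": td, "N1_N": np.nan, "N2_N": np.nan,
                             "Fp_N": np.nan, "Fv_N": np.nan, "k": np.nan,
                             "beyond_limit": False, "singular": True})
    return pd.DataFrame(rows)
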