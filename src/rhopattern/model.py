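"""Core kinetics of the Rho-GEF-myosin activator-inhibitor network.

The dimensional model tracks active/inactive pairs of three species --
Rho GTPase (R), its exchange factor GEF-H1 (G) and myosin (M) -- whose
totals are conserved.  Conservation halves the system to three ODEs for
the active fractions; a quasi-steady-state approximation (QSSA) for the
fast GEF kinetics and a nondimensionalization then reduce the dynamics
to two variables,

    du/dt = f(u, v),    dv/dt = g(u, v),

where ``u`` is dimensionless active Rho (the activator, with positive
feedback through GEF recruitment) and ``v`` is dimensionless active
myosin (the inhibitor, shutting GEF down).  All downstream analysis --
equilibria, bifurcations, Turing instability and PDE simulation -- runs
on the kinetics (``reaction_f``, ``reaction_g``) and their analytic
Jacobian defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DimParams",
    "DimState",
    "NondimParams",
    "NondimScales",
    "StatePoint",
    "Jacobian2",
    "reaction_f",
    "reaction_g",
    "jacobian",
    "dimensional_rhs6",
    "reduced_rhs3",
    "qssa_ga",
    "nondim_map",
    "TABLE1_RANGES",
]

# Published plausible ranges for the dimensional rate constants
# (concentration unit U = molecules/cell, time in seconds).  Values
# outside a range are legal but logged, since they leave the regime the
# model was calibrated for.  GT has no published range ("varies").
TABLE1_RANGES = {
    "k1": (0.0966, 13.049),
    "k2": (0.0652, 2.160),
    "k3": (0.723, 3.34),
    "k4": (1.0, 14.9),
    "k5": (0.0472, 1.0),
    "k6": (0.00933, 0.1),
    "Km1": (0.0886, 2.43),
    "Km2": (0.0741, 0.564),
    "Km3": (0.0033, 0.5),
    "Km4": (0.258, 1.83),
    "RT": (0.443, 1.0),
    "MT": (1.0, 1.24),
}


@dataclass(frozen=True)
class DimParams:
    """Dimensional rate constants and totals.

    Units: k1, k5 in 1/s; k2, k6 in U/s; k3, k4 in 1/(U s); the
    Michaelis constants Km1..Km4 and the totals RT, GT, MT in U.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    Km1: float
    Km2: float
    Km3: float
    Km4: float
    RT: float
    GT: float
    MT: float

    def __post_init__(self):
        for f in fields(self):
            val = getattr(self, f.name)
            if not val > 0:
                raise ValueError(f"{f.name} must be strictly positive, got {val}")
            rng = TABLE1_RANGES.get(f.name)
            if rng is not None and not (rng[0] <= val <= rng[1]):
                logger.warning(
                    "%s=%g outside the calibrated range [%g, %g]",
                    f.name, val, rng[0], rng[1],
                )


@dataclass(frozen=True)
class DimState:
    """Concentrations (U) of the six species; all nonnegative."""

    Ra: float
    Ri: float
    Ga: float
    Gi: float
    Ma: float
    Mi: float

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be nonnegative")


@dataclass(frozen=True)
class NondimParams:
    """Dimensionless parameter vector of the reduced kinetics.

    a1 scales the positive feedback and is proportional to total GEF
    (the natural bifurcation parameter); a2 and a6 are the dimensionless
    totals of Rho and myosin (upper bounds for u and v); a3, a5, a7, a8
    are rescaled Michaelis constants; a4 is the ratio of GEF inhibition
    to GEF activation rates.
    """

    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    a6: float
    a7: float
    a8: float

    def __post_init__(self):
        for f in fields(self):
            if not getattr(self, f.name) > 0:
                raise ValueError(f"{f.name} must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3, self.a4,
                         self.a5, self.a6, self.a7, self.a8])

    def replace(self, **kw) -> "NondimParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class NondimScales:
    """Scale factors mapping dimensional to dimensionless variables.

    u = Ra / u_scale, v = Ma / v_scale, tau = t / t_scale.
    """

    u_scale: float
    v_scale: float
    t_scale: float


@dataclass(frozen=True)
class StatePoint:
    """A point (u, v) in the reduced phase plane."""

    u: float
    v: float


@dataclass(frozen=True)
class Jacobian2:
    """2x2 Jacobian of (f, g) at a state point."""

    fu: float
    fv: float
    gu: float
    gv: float

    @property
    def trace(self) -> float:
        return self.fu + self.gv

    @property
    def det(self) -> float:
        return self.fu * self.gv - self.fv * self.gu

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.fu, self.fv], [self.gu, self.gv]])


def reaction_f(u, v, p: NondimParams):
    """Activator kinetics f(u, v).

    f = a1 u (a2-u) / [(a3+a2-u)(a4 v+u)] - u/(a5+u).

    Accepts scalars or arrays.  The removable singularity at
    u = v = 0 is regularized to f = 0 (the limit along the invariant
    line u = 0).  Points at the pole u = a2 + a3 raise ``ValueError``.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    d1 = p.a3 + p.a2 - u
    d2 = p.a4 * v + u
    if np.any(d1 == 0):
        raise ValueError("f undefined: u at the pole a2 + a3")
    origin = (u == 0) & (v == 0)
    d2_safe = np.where(origin, 1.0, d2)
    if np.any(d2_safe == 0):
        raise ValueError("f undefined: a4*v + u = 0 at u != 0 is inadmissible")
    out = p.a1 * u * (p.a2 - u) / (d1 * d2_safe) - u / (p.a5 + u)
    out = np.where(origin, 0.0, out)
    return float(out) if out.ndim == 0 else out


def reaction_g(u, v, p: NondimParams):
    """Inhibitor kinetics g(u, v).

    g = u (a6-v) / (a7+a6-v) - v/(a8+v).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    d1 = p.a7 + p.a6 - v
    if np.any(d1 == 0):
        raise ValueError("g undefined: v at the pole a6 + a7")
    out = u * (p.a6 - v) / d1 - v / (p.a8 + v)
    return float(out) if out.ndim == 0 else out


def jacobian(u, v, p: NondimParams) -> Jacobian2:
    """Analytic Jacobian of (f, g) at (u, v).

    Closed forms (symbolically verified against the kinetics):
      fu = -a1 [a3 (a4 v (2u - a2) + u^2) - a4 v (u - a2)^2]
           / [(a2+a3-u)^2 (a4 v + u)^2]  -  a5/(a5+u)^2
      fv = -a1 a4 u (a2-u) / [(a2+a3-u)(a4 v+u)^2]
      gu = (a6-v)/(a6+a7-v)
      gv = -a7 u/(a6+a7-v)^2 - a8/(a8+v)^2
    """
    a1, a2, a3, a4, a5, a6, a7, a8 = p.as_array()
    d1 = a2 + a3 - u
    d2 = a4 * v + u
    d3 = a6 + a7 - v
    if d1 == 0 or d2 == 0 or d3 == 0:
        raise ValueError("Jacobian undefined at a kinetic pole")
    fu = (-a1 * (a3 * (a4 * v * (2 * u - a2) + u ** 2) - a4 * v * (u - a2) ** 2)
          / (d1 ** 2 * d2 ** 2) - a5 / (a5 + u) ** 2)
    fv = -a1 * a4 * u * (a2 - u) / (d1 * d2 ** 2)
    gu = (a6 - v) / d3
    gv = -a7 * u / d3 ** 2 - a8 / (a8 + v) ** 2
    return Jacobian2(fu=float(fu), fv=float(fv), gu=float(gu), gv=float(gv))


def dimensional_rhs6(s: DimState, p: DimParams) -> np.ndarray:
    """Rates (U/s) of the six-species dimensional model.

    Returns (dRa, dRi, dGa, dGi, dMa, dMi).  Each inactive-species rate
    is exactly the negative of its active partner, so the three totals
    are conserved by construction.
    """
    act_R = p.k1 * s.Ga * s.Ri / (p.Km1 + s.Ri)
    inh_R = p.k2 * s.Ra / (p.Km2 + s.Ra)
    act_G = p.k3 * s.Ra * s.Gi
    inh_G = p.k4 * s.Ma * s.Ga
    act_M = p.k5 * s.Ra * s.Mi / (p.Km3 + s.Mi)
    inh_M = p.k6 * s.Ma / (p.Km4 + s.Ma)
    dRa = act_R - inh_R
    dGa = act_G - inh_G
    dMa = act_M - inh_M
    return np.array([dRa, -dRa, dGa, -dGa, dMa, -dMa])


def reduced_rhs3(Ra: float, Ga: float, Ma: float, p: DimParams) -> np.ndarray:
    """Rates (U/s) of the conservation-reduced three-ODE model.

    Exactly ``dimensional_rhs6`` evaluated at the state
    (Ra, RT-Ra, Ga, GT-Ga, Ma, MT-Ma), bit for bit.
    """
    if not (0 <= Ra <= p.RT and 0 <= Ga <= p.GT and 0 <= Ma <= p.MT):
        raise ValueError("active concentrations must lie in [0, total]")
    full = dimensional_rhs6(
        DimState(Ra=Ra, Ri=p.RT - Ra, Ga=Ga, Gi=p.GT - Ga,
                 Ma=Ma, Mi=p.MT - Ma), p)
    return full[[0, 2, 4]]


def qssa_ga(Ra: float, Ma: float, p: DimParams) -> float:
    """Quasi-steady-state level of active GEF.

    Root of the Ga-equation: Ga* = GT k3 Ra / (k3 Ra + k4 Ma).  The
    doubly degenerate point Ra = Ma = 0 returns 0 with a logged note.
    """
    denom = p.k3 * Ra + p.k4 * Ma
    if denom == 0:
        logger.info("qssa_ga degenerate at Ra = Ma = 0; returning 0")
        return 0.0
    return p.GT * p.k3 * Ra / denom


def nondim_map(p: DimParams) -> tuple[NondimParams, NondimScales]:
    """Map dimensional parameters to the dimensionless vector a1..a8.

    The scalings are chosen so that substituting the QSSA expression
    for GEF into the reduced three-ODE model and rescaling
    u = Ra/u_scale, v = Ma/v_scale, tau = t/t_scale reproduces
    (f, g) exactly:

        u_scale = k6/k5,  v_scale = k6^2/(k2 k5),  t_scale = k6/(k2 k5)

        a1 = k1 GT / k2        a2 = RT / u_scale   a3 = Km1 / u_scale
        a4 = k4 k6 / (k2 k3)   a5 = Km2 / u_scale  a6 = MT / v_scale
        a7 = Km3 / v_scale     a8 = Km4 / v_scale

    a1 is proportional to GT with everything else fixed, matching its
    role as the experimentally motivated bifurcation parameter.
    """
    u_scale = p.k6 / p.k5
    v_scale = p.k6 ** 2 / (p.k2 * p.k5)
    t_scale = p.k6 / (p.k2 * p.k5)
    params = NondimParams(
        a1=p.k1 * p.GT / p.k2,
        a2=p.RT / u_scale,
        a3=p.Km1 / u_scale,
        a4=p.k4 * p.k6 / (p.k2 * p.k3),
        a5=p.Km2 / u_scale,
        a6=p.MT / v_scale,
        a7=p.Km3 / v_scale,
        a8=p.Km4 / v_scale,
    )
    return params, NondimScales(u_scale=u_scale, v_scale=v_scale, t_scale=t_scale)
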