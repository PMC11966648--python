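"""Diffusion-driven (Turing) instability analysis.

Linearizing the reaction-diffusion system

    u_t = gamma f + u_xx,    v_t = gamma g + d v_xx

about a uniform steady state and expanding in Neumann cosine modes
cos(k x), k = n pi / L, gives the dispersion relation

    lambda^2 - [gamma T - k^2 (1 + d)] lambda
             + [d k^4 - gamma (d fu + gv) k^2 + gamma^2 D] = 0,

with T, D the trace and determinant of the kinetic Jacobian.  A stable
state (T < 0, D > 0) loses stability to a band of wavenumbers iff
d fu + gv > 0 and (d fu + gv)^2 >= 4 d D.  The marginal case defines the
critical diffusion ratio d_c; instability in this activator-inhibitor
model requires d above the larger root (inhibitor diffusing faster).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equilibria import classify_equilibrium, find_steady_states
from .model import Jacobian2, NondimParams

__all__ = [
    "SpatialConfig",
    "DDIFlags",
    "TuringResult",
    "ddi_check",
    "critical_diffusion",
    "dispersion_growth",
    "unstable_band",
    "turing_space_scan",
]


@dataclass(frozen=True)
class SpatialConfig:
    """Spatial parameters: diffusion ratio d (on v), kinetics scaling
    gamma, and domain length L (dimensionless)."""

    d: float
    gamma: float
    L: float = 1.0

    def __post_init__(self):
        if not (self.d > 0 and self.gamma > 0 and self.L > 0):
            raise ValueError("d, gamma and L must be strictly positive")


@dataclass(frozen=True)
class DDIFlags:
    """The four diffusion-driven-instability conditions."""

    trace_negative: bool        # T < 0 (stable without diffusion)
    det_positive: bool          # D > 0
    cross_positive: bool        # d fu + gv > 0
    discriminant_ok: bool       # (d fu + gv)^2 >= 4 d D

    def all(self) -> bool:
        return (self.trace_negative and self.det_positive
                and self.cross_positive and self.discriminant_ok)


@dataclass(frozen=True)
class TuringResult:
    flags: DDIFlags
    dc_minus: float | None
    dc_plus: float | None
    band: tuple[float, float] | None     # (k2_minus, k2_plus)
    modes: tuple[int, ...]


def ddi_check(J: Jacobian2, cfg: SpatialConfig) -> DDIFlags:
    """Evaluate the four Turing conditions for Jacobian J at diffusion
    ratio cfg.d (gamma does not enter the conditions)."""
    T, D = J.trace, J.det
    cross = cfg.d * J.fu + J.gv
    return DDIFlags(
        trace_negative=bool(T < 0),
        det_positive=bool(D > 0),
        cross_positive=bool(cross > 0),
        discriminant_ok=bool(cross * cross >= 4 * cfg.d * D),
    )


def critical_diffusion(J: Jacobian2) -> tuple[float, float]:
    """Roots of the marginal-stability quadratic in d,

        fu^2 d^2 + (4 fv gu - 2 fu gv) d + gv^2 = 0,

    i.e. the diffusion ratios at which the dispersion minimum touches
    zero ((d fu + gv)^2 = 4 d D).  Requires a stable steady state with
    fu > 0.  Raises ``ValueError`` when the roots are complex (no d
    yields instability).
    """
    if not (J.trace < 0 and J.det > 0):
        raise ValueError("critical diffusion requires a stable steady state")
    if not J.fu > 0:
        raise ValueError("critical diffusion requires an activator (fu > 0)")
    coeffs = [J.fu ** 2, 4 * J.fv * J.gu - 2 * J.fu * J.gv, J.gv ** 2]
    roots = np.roots(coeffs)
    if np.any(np.abs(roots.imag) > 1e-12 * max(1.0, np.abs(roots.real).max())):
        raise ValueError("complex critical-diffusion roots: DDI impossible "
                         "for any d")
    lo, hi = sorted(roots.real)
    return float(lo), float(hi)


def dispersion_growth(J: Jacobian2, cfg: SpatialConfig, k2) -> np.ndarray | float:
    """Largest real part of the dispersion roots lambda(k^2).

    Vectorized over ``k2``.  At k^2 = 0 this reduces to the temporal
    eigenvalue problem scaled by gamma.
    """
    k2 = np.asarray(k2, dtype=float)
    g = cfg.gamma
    b = g * J.trace - k2 * (1.0 + cfg.d)
    c = cfg.d * k2 ** 2 - g * (cfg.d * J.fu + J.gv) * k2 + g ** 2 * J.det
    disc = b * b - 4 * c
    sq = np.sqrt(np.abs(disc))
    out = np.where(disc >= 0, (b + sq) / 2, b / 2)
    return float(out) if out.ndim == 0 else out


def unstable_band(J: Jacobian2, cfg: SpatialConfig) -> TuringResult:
    """Unstable wavenumber band and admissible Neumann modes.

    The band is the pair of roots in k^2 of

        h(k^2) = d k^4 - gamma (d fu + gv) k^2 + gamma^2 D = 0,

    inside which Re lambda > 0; the admissible modes are the integers
    n >= 1 with (n pi / L)^2 strictly inside the band (modes touching
    the band edge are marginal, not growing, and excluded).
    """
    flags = ddi_check(J, cfg)
    try:
        dc = critical_diffusion(J)
    except ValueError:
        dc = (None, None)
    band = None
    modes: tuple[int, ...] = ()
    if flags.all():
        g = cfg.gamma
        disc = (g * (cfg.d * J.fu + J.gv)) ** 2 - 4 * cfg.d * g ** 2 * J.det
        if disc > 0:
            sq = np.sqrt(disc)
            mid = g * (cfg.d * J.fu + J.gv)
            k2m = (mid - sq) / (2 * cfg.d)
            k2p = (mid + sq) / (2 * cfg.d)
            band = (float(k2m), float(k2p))
            n_hi = int(np.floor(np.sqrt(k2p) * cfg.L / np.pi)) + 1
            modes = tuple(n for n in range(1, n_hi + 1)
                          if k2m < (n * np.pi / cfg.L) ** 2 < k2p)
    return TuringResult(flags=flags, dc_minus=dc[0], dc_plus=dc[1],
                        band=band, modes=modes)


def turing_space_scan(param_x: str, param_y: str, x_values, y_values,
                      d_values, p_rest: NondimParams) -> pd.DataFrame:
    """Boolean Turing-space scan over a pairwise parameter grid.

    For each grid point the steady states are recomputed; the flag for a
    given d is true iff some stable equilibrium with the (+,-;+,-) sign
    pattern passes all four DDI conditions at that d.  Output is long
    format with columns (param_x, param_y, d, turing).
    """
    for name in (param_x, param_y):
        if name not in {f"a{i}" for i in range(1, 9)}:
            raise ValueError(f"unknown parameter {name!r}")
    rows = []
    for y in np.asarray(y_values, float):
        for x in np.asarray(x_values, float):
            p = p_rest.replace(**{param_x: float(x), param_y: float(y)})
            flags_by_d = {d: False for d in d_values}
            try:
                states = find_steady_states(p)
            except ValueError:
                states = []
            for pt in states:
                try:
                    rec = classify_equilibrium(pt, p)
                except ValueError:
                    continue
                if not (rec.stable and rec.ddi_candidate):
                    continue
                for d in d_values:
                    if ddi_check(rec.jac, SpatialConfig(d=d, gamma=1.0)).all():
                        flags_by_d[d] = True
            for d in d_values:
                rows.append({param_x: x, param_y: y, "d": d,
                             "turing": flags_by_d[d]})
    return pd.DataFrame(rows)
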