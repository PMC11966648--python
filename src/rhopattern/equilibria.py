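"""Uniform steady states of the reduced kinetics and their linear stability.

The v-nullcline g(u, v) = 0 is a quadratic in v once denominators are
cleared, so every steady state lies at the intersection of a nullcline
branch with a sign change of f along it.  Candidates from a u-grid scan
are polished by damped Newton iteration on (f, g) and classified from
the closed-form eigenvalues of the 2x2 Jacobian.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import Jacobian2, NondimParams, StatePoint, jacobian, reaction_f, reaction_g

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityRecord",
    "solve_v_nullcline",
    "find_steady_states",
    "eigenvalues_2x2",
    "classify_equilibrium",
    "records_to_frame",
]

#: classification labels
STABLE_NODE = "stable-node"
STABLE_SPIRAL = "stable-spiral"
UNSTABLE_NODE = "unstable-node"
UNSTABLE_SPIRAL = "unstable-spiral"
SADDLE = "saddle"
MARGINAL = "marginal"

_MARGINAL_TOL = 1e-9
_DEDUP_RADIUS = 1e-6


@dataclass(frozen=True)
class StabilityRecord:
    """Full linear-stability report for one uniform steady state."""

    point: StatePoint
    jac: Jacobian2
    eigenvalues: tuple[complex, complex]
    classification: str
    sign_pattern: tuple[tuple[int, int], tuple[int, int]]
    ddi_candidate: bool

    @property
    def stable(self) -> bool:
        return self.classification in (STABLE_NODE, STABLE_SPIRAL)


def solve_v_nullcline(u: float, p: NondimParams) -> list[float]:
    """All admissible roots v >= 0 of g(u, v) = 0 at fixed u.

    Clearing denominators in g turns the nullcline into the quadratic

        (1 - u) v^2 + [u (a6 - a8) - (a6 + a7)] v + u a6 a8 = 0.

    Roots with v < 0 or v >= a6 + a7 (where the cleared form no longer
    corresponds to g = 0 with positive denominators) are discarded.
    """
    if u < 0:
        raise ValueError("u must be nonnegative")
    A = 1.0 - u
    B = u * (p.a6 - p.a8) - (p.a6 + p.a7)
    C = u * p.a6 * p.a8
    if abs(A) < 1e-14:
        roots = [] if B == 0 else [-C / B]
    else:
        disc = B * B - 4 * A * C
        if disc < 0:
            return []
        sq = np.sqrt(disc)
        roots = [(-B + sq) / (2 * A), (-B - sq) / (2 * A)]
    return sorted(v for v in roots if 0 <= v < p.a6 + p.a7)


def _newton_polish(u0: float, v0: float, p: NondimParams,
                   tol: float = 1e-12, max_iter: int = 60):
    """Damped Newton on (f, g); returns (u, v) or None on failure."""
    u, v = u0, v0
    for _ in range(max_iter):
        try:
            r = np.array([reaction_f(u, v, p), reaction_g(u, v, p)])
        except ValueError:
            return None
        if max(abs(r[0]), abs(r[1])) < tol:
            return u, v
        J = jacobian(u, v, p).as_matrix()
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            return None
        lam = 1.0
        for _ in range(30):
            un, vn = u + lam * step[0], v + lam * step[1]
            if un > 0 and 0 <= vn < p.a6 + p.a7 and un < p.a2 + p.a3:
                try:
                    rn = np.array([reaction_f(un, vn, p), reaction_g(un, vn, p)])
                except ValueError:
                    lam *= 0.5
                    continue
                if np.linalg.norm(rn) < np.linalg.norm(r) or lam < 1e-3:
                    u, v = un, vn
                    break
            lam *= 0.5
        else:
            return None
    r = np.array([reaction_f(u, v, p), reaction_g(u, v, p)])
    return (u, v) if max(abs(r[0]), abs(r[1])) < tol else None


def find_steady_states(p: NondimParams, n_grid: int = 400) -> list[StatePoint]:
    """All steady states of (f, g) inside the trapping box, sorted by u.

    Seeds come from sign changes of f along each branch of the
    v-nullcline over a u-grid of ``n_grid`` points in (0, a2); each seed
    is bracketed by Brent's method and polished by Newton to residual
    below 1e-12, then deduplicated with radius 1e-6.  The degenerate
    boundary point (0, 0), where f is singular, is not reported.
    """
    us = np.linspace(p.a2 * 1e-7, p.a2 * (1 - 1e-9), n_grid)
    found: list[tuple[float, float]] = []
    for branch in (0, 1):
        vals = np.full(n_grid, np.nan)
        for i, u in enumerate(us):
            roots = solve_v_nullcline(u, p)
            if len(roots) > branch:
                vals[i] = reaction_f(u, roots[branch], p)
        for i in range(n_grid - 1):
            if not (np.isfinite(vals[i]) and np.isfinite(vals[i + 1])):
                continue
            if vals[i] == 0.0:
                found.append((us[i], solve_v_nullcline(us[i], p)[branch]))
                continue
            if vals[i] * vals[i + 1] < 0:
                def along(u):
                    roots = solve_v_nullcline(u, p)
                    return reaction_f(u, roots[branch], p)
                try:
                    ur = brentq(along, us[i], us[i + 1], xtol=1e-13)
                except ValueError:
                    continue
                vr = solve_v_nullcline(ur, p)[branch]
                polished = _newton_polish(ur, vr, p)
                if polished is None:
                    warnings.warn(
                        f"Newton polishing failed near (u,v)=({ur:.4g},{vr:.4g});"
                        " seed dropped")
                    continue
                found.append(polished)
    unique: list[tuple[float, float]] = []
    for pt in sorted(found):
        if not any(np.hypot(pt[0] - q[0], pt[1] - q[1]) < _DEDUP_RADIUS
                   for q in unique):
            unique.append(pt)
    return [StatePoint(u=u, v=v) for u, v in unique]


def eigenvalues_2x2(J: Jacobian2) -> tuple[complex, complex]:
    """Closed-form eigenvalues of a 2x2 Jacobian.

    Roots of lambda^2 - T lambda + D, ordered by descending real part,
    then descending imaginary part.
    """
    T, D = J.trace, J.det
    disc = T * T - 4 * D
    if disc >= 0:
        sq = np.sqrt(disc)
        lams = [complex((T + sq) / 2), complex((T - sq) / 2)]
    else:
        sq = np.sqrt(-disc)
        lams = [complex(T / 2, sq / 2), complex(T / 2, -sq / 2)]
    lams.sort(key=lambda z: (-z.real, -z.imag))
    return lams[0], lams[1]


def _sign(x: float, tol: float = 1e-12) -> int:
    if x > tol:
        return 1
    if x < -tol:
        return -1
    return 0


def classify_equilibrium(point: StatePoint, p: NondimParams,
                         residual_tol: float = 1e-8) -> StabilityRecord:
    """Linear classification of a steady state of (f, g).

    The point must satisfy |f|, |g| < ``residual_tol``.  An equilibrium
    is *marginal* when |max Re lambda| < 1e-9, a *spiral* when
    |Im lambda| > 1e-9, a *saddle* when det < 0.  The DDI-candidate flag
    marks stable states with the activator-inhibitor sign pattern
    (+,-;+,-), the only ones diffusion can destabilize.
    """
    r_f = reaction_f(point.u, point.v, p)
    r_g = reaction_g(point.u, point.v, p)
    if max(abs(r_f), abs(r_g)) > residual_tol:
        raise ValueError(
            f"({point.u}, {point.v}) is not a steady state: residual "
            f"({r_f:.3g}, {r_g:.3g})")
    J = jacobian(point.u, point.v, p)
    lam1, lam2 = eigenvalues_2x2(J)
    max_re = max(lam1.real, lam2.real)
    spiral = abs(lam1.imag) > _MARGINAL_TOL
    if J.det < 0:
        cls = SADDLE
    elif abs(max_re) < _MARGINAL_TOL:
        cls = MARGINAL
    elif max_re < 0:
        cls = STABLE_SPIRAL if spiral else STABLE_NODE
    else:
        cls = UNSTABLE_SPIRAL if spiral else UNSTABLE_NODE
    pattern = ((_sign(J.fu), _sign(J.fv)), (_sign(J.gu), _sign(J.gv)))
    stable = cls in (STABLE_NODE, STABLE_SPIRAL)
    ddi = stable and pattern == ((1, -1), (1, -1))
    return StabilityRecord(point=point, jac=J, eigenvalues=(lam1, lam2),
                           classification=cls, sign_pattern=pattern,
                           ddi_candidate=ddi)


def records_to_frame(records: list[StabilityRecord]) -> pd.DataFrame:
    """Tabulate stability records (one row per equilibrium) for CSV export."""
    rows = []
    for r in records:
        l1, l2 = r.eigenvalues
        rows.append({
            "u": r.point.u, "v": r.point.v,
            "fu": r.jac.fu, "fv": r.jac.fv, "gu": r.jac.gu, "gv": r.jac.gv,
            "re_lambda1": l1.real, "im_lambda1": l1.imag,
            "re_lambda2": l2.real, "im_lambda2": l2.imag,
            "class": r.classification, "ddi_candidate": r.ddi_candidate,
        })
    return pd.DataFrame(rows)
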