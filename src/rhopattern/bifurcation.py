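"""Parameter sweeps, Hopf/fold detection and dynamical-region classification.

The one-parameter structure of this model is simple enough (branches
single-valued in a1 away from folds) that continuation is done by a
dense sweep with bisection refinement of bracketed events rather than
pseudo-arclength.  The (a1, a5) plane decomposes into five regions:

    I    one stable state, no Turing sign pattern
    II   one stable state, Turing candidate (+,-;+,-)
    III  one unstable state (stable limit cycle by Poincare-Bendixson)
    IV   three states, two stable and a saddle (bistable)
    V    three states, one stable, a saddle and an unstable spiral
         (stable state coexisting with a stable limit cycle)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._peaks import peak_metrics
from .equilibria import StabilityRecord, classify_equilibrium, find_steady_states
from .model import NondimParams, reaction_f, reaction_g

logger = logging.getLogger(__name__)

__all__ = [
    "BranchPoint",
    "LimitCycleMetrics",
    "sweep_branch",
    "refine_event",
    "classify_region",
    "region_map",
    "ode_limit_cycle",
]

REGIONS = ("I", "II", "III", "IV", "V", "boundary")


@dataclass(frozen=True)
class BranchPoint:
    """Equilibria and stability at one value of the swept parameter."""

    value: float
    records: tuple[StabilityRecord, ...]
    events: tuple[str, ...] = ()  # events bracketed since the previous point


@dataclass(frozen=True)
class LimitCycleMetrics:
    period: float
    amplitude: float
    converged: bool


def _classified(p: NondimParams) -> tuple[StabilityRecord, ...]:
    return tuple(classify_equilibrium(pt, p) for pt in find_steady_states(p))


def sweep_branch(p: NondimParams, param_name: str, values) -> list[BranchPoint]:
    """Sweep one parameter, classifying equilibria and flagging events.

    Between consecutive sweep values a *fold* is flagged when the
    equilibrium count changes, and a *hopf* when a matched equilibrium's
    leading real part changes sign with nonzero imaginary part on at
    least one side.
    """
    values = np.asarray(values, float)
    if len(values) < 2:
        raise ValueError("need at least 2 sweep points")
    out: list[BranchPoint] = []
    prev: BranchPoint | None = None
    for val in values:
        pv = p.replace(**{param_name: float(val)})
        recs = _classified(pv)
        if not recs:
            logger.warning("no equilibria at %s=%g", param_name, val)
        events = []
        if prev is not None and prev.records and recs:
            if len(prev.records) != len(recs):
                events.append("fold")
            else:
                for r0, r1 in zip(prev.records, recs):
                    re0 = max(l.real for l in r0.eigenvalues)
                    re1 = max(l.real for l in r1.eigenvalues)
                    osc = (abs(r0.eigenvalues[0].imag) > 1e-9
                           or abs(r1.eigenvalues[0].imag) > 1e-9)
                    if re0 * re1 < 0 and osc:
                        events.append("hopf")
                        break
        out.append(BranchPoint(value=float(val), records=recs,
                               events=tuple(events)))
        prev = out[-1]
    return out


def refine_event(p: NondimParams, param_name: str, bracket: tuple[float, float],
                 kind: str, tol: float = 1e-6) -> float:
    """Bisection refinement of a bracketed bifurcation to parameter tol.

    For a Hopf the indicator is the leading real part of the matched
    equilibrium pair; for a fold it is the equilibrium count.  A bracket
    whose indicator no longer changes raises ``ValueError`` (degenerate
    bracket, e.g. a fold pair annihilating under refinement).
    """
    lo, hi = bracket

    if kind == "hopf":
        def indicator(val):
            recs = _classified(p.replace(**{param_name: val}))
            if not recs:
                return np.nan
            return max(max(l.real for l in r.eigenvalues)
                       for r in recs if abs(r.eigenvalues[0].imag) > 1e-9)
        f_lo, f_hi = indicator(lo), indicator(hi)
        if not (np.isfinite(f_lo) and np.isfinite(f_hi)) or f_lo * f_hi > 0:
            raise ValueError("degenerate hopf bracket: no sign change")
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            f_mid = indicator(mid)
            if f_lo * f_mid <= 0:
                hi = mid
            else:
                lo, f_lo = mid, f_mid
        return 0.5 * (lo + hi)

    if kind == "fold":
        def count(val):
            return len(find_steady_states(p.replace(**{param_name: val})))
        c_lo, c_hi = count(lo), count(hi)
        if c_lo == c_hi:
            raise ValueError("degenerate fold bracket: count does not change")
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if count(mid) == c_lo:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    raise ValueError(f"unknown event kind {kind!r}")


def classify_region(a1: float, a5: float, p_rest: NondimParams) -> str:
    """Label a point of the (a1, a5) plane by its dynamical region.

    Decision table on the classified equilibria: one equilibrium that is
    stable without (with) the DDI sign pattern is I (II); one unstable
    non-saddle equilibrium is III; three equilibria with exactly two
    stable is IV; three with exactly one stable is V.  Anything else --
    including marginal spectra -- is labelled 'boundary'.
    """
    p = p_rest.replace(a1=a1, a5=a5)
    recs = _classified(p)
    if any(r.classification == "marginal" for r in recs):
        return "boundary"
    n = len(recs)
    n_stable = sum(r.stable for r in recs)
    if n == 1:
        r = recs[0]
        if r.stable:
            return "II" if r.ddi_candidate else "I"
        if r.classification != "saddle":
            return "III"
        return "boundary"
    if n == 3:
        if n_stable == 2:
            return "IV"
        if n_stable == 1:
            return "V"
    return "boundary"


def region_map(a1_values, a5_values, p_rest: NondimParams) -> pd.DataFrame:
    """Regular-grid classification of the (a1, a5) plane (long format)."""
    rows = []
    for a5 in np.asarray(a5_values, float):
        for a1 in np.asarray(a1_values, float):
            rows.append({"a1": a1, "a5": a5,
                         "region": classify_region(a1, a5, p_rest)})
    return pd.DataFrame(rows)


def ode_limit_cycle(p: NondimParams, gamma: float = 1.0,
                    t_end: float | None = None,
                    start: tuple[float, float] | None = None,
                    rtol: float = 1e-8, atol: float = 1e-10,
                    n_samples: int = 40_000) -> LimitCycleMetrics:
    """Period and amplitude of the attracting limit cycle of the kinetics.

    Integrates du/dt = gamma f, dv/dt = gamma g with a stiff solver,
    discards the first half of the horizon and extracts the period from
    quadratic-interpolated successive peaks of u(t).  Because gamma only
    rescales time, ``t_end`` defaults to 900/gamma, which spans the same
    number of cycles at every gamma.  The default start is a point
    displaced from the phase-plane centroid, inside the cycle's basin
    for the oscillatory regions of this model.
    """
    if t_end is None:
        t_end = 900.0 / gamma
    if start is None:
        ss = find_steady_states(p)
        if ss:
            start = (max(0.05 * p.a2, 1.5 * ss[0].u), max(0.5, ss[0].v))
        else:
            start = (0.1 * p.a2, 0.1 * p.a6)

    def rhs(t, y):
        return [gamma * reaction_f(y[0], y[1], p),
                gamma * reaction_g(y[0], y[1], p)]

    sol = solve_ivp(rhs, (0.0, t_end), list(start), method="LSODA",
                    rtol=rtol, atol=atol, dense_output=True)
    if not sol.success:
        return LimitCycleMetrics(np.nan, np.nan, False)
    t = np.linspace(t_end / 2, t_end, n_samples)
    u = sol.sol(t)[0]
    period, amplitude, converged, _ = peak_metrics(t, u, min_peaks=4,
                                                   period_tol=1e-3)
    return LimitCycleMetrics(period=period, amplitude=amplitude,
                             converged=converged)
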