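"""Long-time outcome classification and descriptors for PDE runs.

The taxonomy mirrors the behaviours the reaction-diffusion model
exhibits across its dynamical regions: relaxation to a uniform state,
stationary Turing patterns, spatially near-uniform temporal limit
cycles, and travelling fronts between coexisting states in the bistable
regimes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._peaks import peak_metrics
from .pde import PDESolution

__all__ = [
    "OutcomeReport",
    "classify_outcome",
    "dominant_mode",
    "oscillation_metrics",
    "front_speed",
]

OUTCOMES = ("uniform_steady", "turing_pattern", "temporal_oscillation",
            "travelling_front", "undetermined")


@dataclass(frozen=True)
class OutcomeReport:
    outcome: str
    dominant_mode: int = 0
    period: float | None = None
    amplitude: float | None = None
    front_speed: float | None = None
    front_direction: str | None = None   # 'rightward' | 'leftward'
    front_r2: float | None = None
    notes: str = ""


def dominant_mode(u: np.ndarray, x: np.ndarray, L: float,
                  tol_x: float | None = None, n_max: int | None = None) -> int:
    """Index of the dominant Neumann cosine mode of a spatial profile.

    Returns argmax_n |integral u(x) cos(n pi x / L) dx| for n >= 1 when
    the profile's spatial standard deviation exceeds ``tol_x``
    (default 1e-4 times the profile scale), else 0.
    """
    u = np.asarray(u, float)
    scale = max(np.abs(u).max(), 1e-30)
    if tol_x is None:
        tol_x = 1e-4 * scale
    if u.std() <= tol_x:
        return 0
    if n_max is None:
        n_max = max(8, len(x) // 8)
    coeffs = [abs(np.trapezoid(u * np.cos(n * np.pi * x / L), x))
              for n in range(1, n_max + 1)]
    return 1 + int(np.argmax(coeffs))


def oscillation_metrics(t: np.ndarray, signal: np.ndarray,
                        min_peaks: int = 4) -> tuple[float, float]:
    """Period and amplitude of a point signal via interpolated peaks.

    Same estimator as the ODE limit-cycle extractor.  Raises
    ``ValueError`` when fewer than ``min_peaks`` peaks are present.
    """
    period, amplitude, _, peaks = peak_metrics(t, signal, min_peaks=min_peaks)
    if len(peaks) < min_peaks:
        raise ValueError(f"only {len(peaks)} peaks found; need {min_peaks}")
    return period, amplitude


def _front_positions(sol: PDESolution, level: float) -> np.ndarray:
    """Interface position X(t): the x where u crosses ``level``, tracked
    by continuity.

    The first frame seeds the track at the crossing nearest the
    piecewise-IC split (or the leftmost crossing otherwise); each later
    frame picks the crossing nearest the previous position.  Continuity
    tracking keeps the estimate on the travelling interface even when
    secondary crossings appear (e.g. oscillatory transients on the
    invaded side).  Entries are nan when no crossing exists.
    """
    pos = np.full(sol.t.size, np.nan)
    split = getattr(sol.config.ic, "split", None)
    prev = None
    for j in range(sol.t.size):
        prof = sol.u[:, j] - level
        idx = np.nonzero(np.diff(np.sign(prof)) != 0)[0]
        if not idx.size:
            continue
        cand = []
        for i in idx:
            x0, x1 = sol.x[i], sol.x[i + 1]
            y0, y1 = prof[i], prof[i + 1]
            cand.append(x0 if y1 == y0 else x0 + (x1 - x0) * (-y0) / (y1 - y0))
        cand = np.asarray(cand)
        if prev is None:
            target = split if split is not None else cand[0]
            pos[j] = cand[np.argmin(np.abs(cand - target))]
        else:
            pos[j] = cand[np.argmin(np.abs(cand - prev))]
        prev = pos[j]
    return pos


def front_speed(sol: PDESolution, level: float | None = None):
    """Front speed from least squares on the level-crossing trajectory.

    The front position X(t) is the leftmost crossing of ``level``
    (default: midpoint of the two base-state u values for piecewise
    initial conditions, else midpoint of the final profile's range).
    The speed is the slope of the least-squares line through X(t) over
    the middle half of the run.  Returns
    ``(speed, r_squared, monotone, positions)``; a non-monotone X(t)
    is reported, not raised.
    """
    if level is None:
        ic = sol.config.ic
        if ic.kind == "piecewise-front":
            level = 0.5 * (ic.base[0].u + ic.base[1].u)
        else:
            prof = sol.u[:, -1]
            level = 0.5 * (prof.min() + prof.max())
    pos = _front_positions(sol, level)
    n = sol.t.size
    sel = slice(n // 4, 3 * n // 4 + 1)
    t_fit, x_fit = sol.t[sel], pos[sel]
    ok = np.isfinite(x_fit)
    if ok.sum() < 3:
        raise ValueError("front not trackable: too few level crossings")
    t_fit, x_fit = t_fit[ok], x_fit[ok]
    slope, intercept = np.polyfit(t_fit, x_fit, 1)
    resid = x_fit - (slope * t_fit + intercept)
    ss_tot = np.sum((x_fit - x_fit.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 0.0
    dx = np.diff(x_fit)
    monotone = bool(np.all(dx <= 1e-9) or np.all(dx >= -1e-9))
    return float(slope), float(r2), monotone, pos


def classify_outcome(sol: PDESolution, tol_t: float = 1e-6,
                     tol_x_rel: float = 1e-4) -> OutcomeReport:
    """Classify the long-time outcome of a PDE run.

    Decision rules on the final third of the run:

    * L2 time-derivative below ``tol_t`` and spatial sd below
      tol_x = ``tol_x_rel`` x (field scale)  ->  uniform_steady;
    * temporal below, spatial above  ->  turing_pattern (with the
      dominant Neumann mode of the final profile);
    * temporal above with a periodic midpoint signal  ->
      temporal_oscillation (period/amplitude at x = L/2);
    * temporal above with a monotone level-set displacement fitting a
      line with R^2 > 0.99  ->  travelling_front;
    * anything else  ->  undetermined.
    """
    n = sol.t.size
    tail = slice(2 * n // 3, None)
    l2u, l2v = sol.diagnostics["l2_dudt"], sol.diagnostics["l2_dvdt"]
    temporal = max(l2u[2 * (n - 1) // 3:].max(), l2v[2 * (n - 1) // 3:].max())
    scale = max(np.abs(sol.u).max(), 1e-30)
    tol_x = tol_x_rel * scale
    spatial_sd = sol.u[:, -1].std()
    L = sol.config.cfg.L

    if temporal < tol_t:
        if spatial_sd < tol_x:
            return OutcomeReport(outcome="uniform_steady", dominant_mode=0)
        return OutcomeReport(outcome="turing_pattern",
                             dominant_mode=dominant_mode(sol.u[:, -1], sol.x, L))

    # temporal activity: oscillation first, then front
    mid = sol.u[sol.x.size // 2, :]
    t_tail = sol.t[tail]
    sig = mid[tail]
    if sig.max() - sig.min() > tol_x:
        period, amplitude, converged, peaks = peak_metrics(
            t_tail, sig, min_peaks=4, period_tol=0.05)
        if converged:
            return OutcomeReport(outcome="temporal_oscillation",
                                 period=period, amplitude=amplitude)
    try:
        speed, r2, monotone, pos = front_speed(sol)
    except ValueError:
        speed, r2, monotone = None, None, False
    if monotone and r2 is not None and r2 > 0.99 and abs(speed) > 0:
        direction = "rightward" if speed > 0 else "leftward"
        return OutcomeReport(outcome="travelling_front", front_speed=speed,
                             front_direction=direction, front_r2=r2)
    return OutcomeReport(outcome="undetermined",
                         notes=f"temporal={temporal:.3g}, sd={spatial_sd:.3g}")
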