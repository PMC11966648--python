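"""Method-of-lines solver for the 1-D reaction-diffusion system.

    u_t = gamma f(u, v) + u_xx,   v_t = gamma g(u, v) + d v_xx

on [0, L] with zero-flux (Neumann) boundaries, discretized by
second-order central differences on a node-centred uniform grid with
mirrored ghost points, and advanced by LSODA with a banded Jacobian
(the two fields are interleaved, so the bandwidth is 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model import NondimParams, StatePoint, reaction_f, reaction_g
from .turing import SpatialConfig

__all__ = [
    "ICSpec",
    "PDEConfig",
    "PDESolution",
    "laplacian_neumann",
    "make_initial_condition",
    "integrate_rd",
    "l2_time_derivative",
]

IC_KINDS = ("uniform", "mode-perturbed", "mixed-mode", "piecewise-front")


@dataclass(frozen=True)
class ICSpec:
    """Initial-condition recipe.

    kind 'uniform' is the base state exactly; 'mode-perturbed' and
    'mixed-mode' add eps * r(x) * sum_n cos(n pi x / L) over ``modes``
    with independent per-node Uniform[0,1) draws r(x) for each field;
    'piecewise-front' joins two base states at x = ``split`` (first
    state for x <= split), each side perturbed the same way.
    """

    kind: str
    base: tuple[StatePoint, ...]
    eps: float = 1e-3
    modes: tuple[int, ...] = (1,)
    split: float | None = None

    def __post_init__(self):
        if self.kind not in IC_KINDS:
            raise ValueError(f"unknown IC kind {self.kind!r}")
        if self.eps < 0:
            raise ValueError("eps must be nonnegative")
        if self.kind == "piecewise-front":
            if len(self.base) != 2:
                raise ValueError("piecewise-front needs two base states")
            if self.split is None:
                raise ValueError("piecewise-front needs a split point")
        elif len(self.base) != 1:
            raise ValueError(f"{self.kind} needs exactly one base state")


@dataclass(frozen=True)
class PDEConfig:
    p: NondimParams
    cfg: SpatialConfig
    ic: ICSpec
    seed: int
    Nx: int = 200
    t_end: float = 10.0
    n_save: int = 201
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self):
        if self.Nx < 50:
            raise ValueError("Nx must be at least 50")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.ic.kind == "piecewise-front" and not (
                0 < self.ic.split < self.cfg.L):
            raise ValueError("split must lie inside (0, L)")


@dataclass
class PDESolution:
    """Space-time fields with the configuration that produced them."""

    x: np.ndarray            # (Nx,)
    t: np.ndarray            # (nt,)
    u: np.ndarray            # (Nx, nt)
    v: np.ndarray            # (Nx, nt)
    config: PDEConfig
    diagnostics: dict = field(default_factory=dict)


def laplacian_neumann(f: np.ndarray, h: float) -> np.ndarray:
    """Second-order Laplacian with mirrored ghost nodes at both ends.

    The stencil rows sum to zero, so the discrete diffusive flux is
    conservative.
    """
    f = np.asarray(f, float)
    if f.size < 3:
        raise ValueError("field must have at least 3 nodes")
    out = np.empty_like(f)
    out[1:-1] = f[2:] - 2.0 * f[1:-1] + f[:-2]
    out[0] = 2.0 * (f[1] - f[0])
    out[-1] = 2.0 * (f[-2] - f[-1])
    return out / (h * h)


def make_initial_condition(spec: ICSpec, x: np.ndarray, L: float,
                           seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded initial fields (u0, v0) on the grid ``x``.

    The perturbation is eps * r(x) * sum_n cos(n pi x / L) with r(x)
    drawn per node from Uniform[0,1) (independent draws for u and v)
    under ``numpy.random.default_rng(seed)``.  Negative values (possible
    only for large eps) are clipped to zero with a warning.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    shape = np.zeros_like(x)
    for n in spec.modes:
        shape = shape + np.cos(n * np.pi * x / L)
    r_u = rng.random(x.size)
    r_v = rng.random(x.size)

    if spec.kind == "piecewise-front":
        left, right = spec.base
        u_base = np.where(x <= spec.split, left.u, right.u)
        v_base = np.where(x <= spec.split, left.v, right.v)
    else:
        u_base = np.full_like(x, spec.base[0].u)
        v_base = np.full_like(x, spec.base[0].v)

    if spec.kind == "uniform" or spec.eps == 0:
        return u_base.copy(), v_base.copy()

    u0 = u_base + spec.eps * r_u * shape
    v0 = v_base + spec.eps * r_v * shape
    if np.any(u0 < 0) or np.any(v0 < 0):
        warnings.warn("initial condition clipped at zero")
        u0 = np.clip(u0, 0.0, None)
        v0 = np.clip(v0, 0.0, None)
    return u0, v0


def integrate_rd(config: PDEConfig) -> PDESolution:
    """Integrate the reaction-diffusion system by the method of lines.

    The state interleaves (u_i, v_i) per node, making the combined
    reaction + diffusion Jacobian pentadiagonal; LSODA exploits that
    banded structure.  Raises ``RuntimeError`` on integrator failure or
    non-finite fields.
    """
    p, cfg = config.p, config.cfg
    x = np.linspace(0.0, cfg.L, config.Nx)
    h = x[1] - x[0]
    u0, v0 = make_initial_condition(config.ic, x, cfg.L, config.seed)
    y0 = np.empty(2 * config.Nx)
    y0[0::2], y0[1::2] = u0, v0
    t_save = np.linspace(0.0, config.t_end, config.n_save)

    def rhs(t, y):
        u = y[0::2]
        v = y[1::2]
        du = cfg.gamma * reaction_f(u, v, p) + laplacian_neumann(u, h)
        dv = cfg.gamma * reaction_g(u, v, p) + cfg.d * laplacian_neumann(v, h)
        out = np.empty_like(y)
        out[0::2], out[1::2] = du, dv
        return out

    sol = solve_ivp(rhs, (0.0, config.t_end), y0, method="LSODA",
                    t_eval=t_save, rtol=config.rtol, atol=config.atol,
                    lband=2, uband=2)
    if not sol.success:
        raise RuntimeError(f"integration failed at t={sol.t[-1] if len(sol.t) else 0}:"
                           f" {sol.message}")
    u = sol.y[0::2, :]
    v = sol.y[1::2, :]
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise RuntimeError("non-finite fields in PDE solution")
    out = PDESolution(x=x, t=sol.t, u=u, v=v, config=config)
    l2u, l2v = l2_time_derivative(out)
    out.diagnostics = {"l2_dudt": l2u, "l2_dvdt": l2v}
    return out


def l2_time_derivative(sol: PDESolution) -> tuple[np.ndarray, np.ndarray]:
    """Spatial L2 norm of the discrete time derivative per save interval.

    For each consecutive pair of saved frames:
    sqrt( sum_x ((w(x, t+dt) - w(x, t)) / dt)^2 * h ) for w = u, v.
    Decay of this series signals convergence to a stationary (possibly
    patterned) profile.
    """
    if sol.t.size < 2:
        raise ValueError("need at least two saved frames")
    h = sol.x[1] - sol.x[0]
    dt = np.diff(sol.t)
    du = (sol.u[:, 1:] - sol.u[:, :-1]) / dt
    dv = (sol.v[:, 1:] - sol.v[:, :-1]) / dt
    return (np.sqrt(np.sum(du ** 2, axis=0) * h),
            np.sqrt(np.sum(dv ** 2, axis=0) * h))
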