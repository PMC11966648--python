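"""Printed fixtures, parameter recovery and reproducible scenarios.

The original study tabulates, for each dynamical region, the location of
every uniform steady state together with its Jacobian and eigenvalues,
but the underlying dimensionless parameter table is not available.
Because each fixture pins six equations -- f = g = 0 and the four
Jacobian entries -- at a known (a1, a5), the six shared parameters
(a2, a3, a4, a6, a7, a8) are strongly overdetermined by the nine
tabulated states and are recovered here by multistart nonlinear least
squares.  The recovered vector is version-pinned below and regenerated
by the test suite.

Two tabulated entries are internally inconsistent (the real part of one
eigenvalue pair disagrees with the half-trace of its own Jacobian, and
one Jacobian corner has the wrong sign for its printed eigenvalues);
they carry trust flags and are excluded from the fit, never silently
corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .equilibria import eigenvalues_2x2, find_steady_states
from .model import Jacobian2, NondimParams, StatePoint, jacobian, reaction_f, reaction_g
from .pde import ICSpec, PDEConfig
from .turing import SpatialConfig

__all__ = [
    "Fixture",
    "RecoveryResult",
    "Scenario",
    "fixture_table",
    "recover_parameters",
    "set2_params",
    "pattern_scenario_params",
    "make_scenario",
    "SET2_RECOVERED",
    "PATTERN_SCENARIO_RECOVERED",
]

#: Version-pinned recovery results (regenerated by the test suite).
SET2_RECOVERED = {
    "a2": 4.499983992709449,
    "a3": 0.10001129225551196,
    "a4": 2.1052653358697455,
    "a6": 7.500002079733853,
    "a7": 0.6074906061880871,
    "a8": 7.500105977924176,
}

#: (a1, a5) of the Turing-pattern scenario (a3=0.1, a7=16), recovered
#: from its printed steady state and Jacobian with the set-2 (a2, a4).
PATTERN_SCENARIO_RECOVERED = {"a1": 2.999868036733742, "a5": 1.750100719951532}

RECOVERY_FAIL_NORM = 0.05


@dataclass(frozen=True)
class Fixture:
    """One printed steady-state fixture.

    ``trust`` flags individual stored entries; untrusted entries are
    excluded from parameter recovery and consistency checks.
    """

    name: str
    region: str
    u: float
    v: float
    a1: float | None = None
    a5: float | None = None
    jac: Jacobian2 | None = None
    eigenvalues: tuple[complex, complex] | None = None
    trust: dict = field(default_factory=dict)
    in_recovery: bool = True
    note: str = ""


def fixture_table() -> list[Fixture]:
    """All printed fixtures: the nine region I-V states (set 2), the
    Turing-analysis point, and the three set-1 phase-plane states.

    Set-1 fixtures carry eigenvalues only (no Jacobians were printed)
    and are excluded from recovery: they belong to a different parameter
    set and are printed at lower precision.
    """
    J = Jacobian2
    return [
        Fixture("P1", "I", 0.024877, 0.17634, a1=0.2, a5=2.0,
                jac=J(-0.0250, -0.0653, 0.9234, -0.12752),
                eigenvalues=(complex(-0.07626, 0.2404), complex(-0.07626, -0.2404))),
        Fixture("P2", "II", 0.1270, 0.9864, a1=2.0, a5=1.0,
                jac=J(0.0483, -0.1077, 0.9147, -0.1057),
                eigenvalues=(complex(-0.0287, 0.3043), complex(-0.0287, -0.3043))),
        Fixture("P3", "III", 0.34649, 3.2612, a1=4.0, a5=1.5,
                jac=J(0.0745, -0.0548, 0.8747, -0.0737),
                eigenvalues=(complex(0.0004, 0.2059), complex(0.0004, -0.2059))),
        Fixture("P4", "IV", 0.49027, 4.9289, a1=4.3, a5=2.1,
                jac=J(0.0545, -0.0367, 0.8089, -0.0780),
                eigenvalues=(complex(-0.1176, 0.1589), complex(-0.1176, -0.1589)),
                trust={"eig_real": False},
                note="printed eigenvalue real part -0.1176 disagrees with "
                     "half-trace -0.01175 of the printed Jacobian"),
        Fixture("P5", "IV", 2.1613, 7.32, a1=4.3, a5=2.1,
                jac=J(0.08127, -0.0608, 0.2285, -2.1515),
                eigenvalues=(complex(0.0750), complex(-2.1453))),
        Fixture("P6", "IV", 4.2307, 7.4191, a1=4.3, a5=2.1,
                jac=J(-0.6002, -0.0709, 0.1175, 5.4569),
                eigenvalues=(complex(-0.6020), complex(-5.4552)),
                trust={"gv": False},
                note="printed gv=+5.4569 has the wrong sign for the printed "
                     "eigenvalues (-0.6020, -5.4552), which imply -5.4569"),
        Fixture("P7", "V", 0.43116, 4.2716, a1=5.0, a5=1.5,
                jac=J(0.0906, -0.0499, 0.8416, -0.0719),
                eigenvalues=(complex(0.0093, 0.1881), complex(0.0093, -0.1881))),
        Fixture("P8", "V", 2.1663, 7.3206, a1=5.0, a5=1.5,
                jac=J(0.1171, -0.0708, 0.2280, -2.1593),
                eigenvalues=(complex(0.110), complex(-2.1522))),
        Fixture("P9", "V", 4.2787, 7.4201, a1=5.0, a5=1.5,
                jac=J(-0.9506, -0.0783, 0.1162, -5.5347),
                eigenvalues=(complex(-0.9526), complex(-5.5328))),
        # Turing-analysis point: a3=0.1, a7=16 override; its own (a1, a5)
        # are recovered separately (pattern_scenario_params).
        Fixture("Turing", "II", 2.3176, 4.4414,
                jac=J(0.07980, -0.1028, 0.16048, -0.15468),
                in_recovery=False,
                note="computed with a3=0.1, a7=16"),
        # Set-1 phase-plane states (different parameter set, eigenvalues
        # only, comma-decimal printing interpreted as periods).
        Fixture("P11", "set1-stable", 0.18674, 0.7666,
                eigenvalues=(complex(-0.184, 0.395), complex(-0.184, -0.395)),
                in_recovery=False),
        Fixture("P12", "set1-stable", 1.168, 4.9796,
                eigenvalues=(complex(-0.193, 0.182), complex(-0.193, -0.182)),
                in_recovery=False),
        Fixture("P13", "set1-oscillatory", 0.59759, 2.8004,
                eigenvalues=(complex(0.025, 0.231), complex(0.025, -0.231)),
                in_recovery=False),
    ]


@dataclass(frozen=True)
class RecoveryResult:
    params: dict                 # recovered {a2, a3, a4, a6, a7, a8}
    residual_norm: float
    max_residual: float
    per_fixture: dict            # name -> {equation: residual}
    success: bool
    n_starts: int


def _recovery_residuals(q: np.ndarray, fixtures: list[Fixture]):
    """Stacked residuals [f, g, fu, fv, gu, gv] over trusted entries."""
    a2, a3, a4, a6, a7, a8 = q
    rows = []
    labels = []
    for fx in fixtures:
        n_eq = 2 + sum(fx.trust.get(k, True) for k in ("fu", "fv", "gu", "gv"))
        if fx.u >= a2 + a3 or fx.v >= a6 + a7 or min(a2 - fx.u, 0) < 0:
            rows.extend([1e3] * n_eq)
            labels.extend([(fx.name, "penalty")] * n_eq)
            continue
        p = NondimParams(a1=fx.a1, a2=a2, a3=a3, a4=a4, a5=fx.a5,
                         a6=a6, a7=a7, a8=a8)
        vals = {"f": reaction_f(fx.u, fx.v, p), "g": reaction_g(fx.u, fx.v, p)}
        J = jacobian(fx.u, fx.v, p)
        printed = {"fu": fx.jac.fu, "fv": fx.jac.fv,
                   "gu": fx.jac.gu, "gv": fx.jac.gv}
        for k in ("fu", "fv", "gu", "gv"):
            if fx.trust.get(k, True):
                vals[k] = getattr(J, k) - printed[k]
        for k, r in vals.items():
            r = r if np.isfinite(r) else 1e3
            rows.append(r)
            labels.append((fx.name, k))
    return np.asarray(rows), labels


def recover_parameters(fixtures: list[Fixture] | None = None,
                       n_starts: int = 20, seed: int = 0) -> RecoveryResult:
    """Least-squares recovery of the shared parameters (a2,a3,a4,a6,a7,a8).

    Minimizes the stacked residuals of f, g and the trusted Jacobian
    entries over all recovery fixtures, with each fixture's printed
    (a1, a5) held fixed.  Multistart in log space (log-uniform starts in
    [1e-2, 1e2]); the fit is declared failed when the residual norm
    exceeds 0.05.
    """
    if fixtures is None:
        fixtures = [f for f in fixture_table() if f.in_recovery]
    if sum(f.a1 is not None for f in fixtures) < 2:
        raise ValueError("need at least two fixtures with printed (a1, a5)")
    rng = np.random.default_rng(seed)

    def fun(logq):
        with np.errstate(all="ignore"):
            return _recovery_residuals(np.exp(np.clip(logq, -30, 30)),
                                       fixtures)[0]

    best = None
    for i in range(n_starts):
        x0 = (np.log(rng.uniform(1e-2, 1e2, 6)) if i
              else np.log([1.0, 1.0, 1.0, 5.0, 1.0, 5.0]))
        try:
            fit = least_squares(fun, x0, method="lm", max_nfev=50_000)
        except Exception:
            continue
        if best is None or fit.cost < best.cost:
            best = fit
    if best is None:
        raise RuntimeError("all recovery starts failed")
    q = np.exp(best.x)
    res, labels = _recovery_residuals(q, fixtures)
    per_fixture: dict = {}
    for (name, eq), r in zip(labels, res):
        per_fixture.setdefault(name, {})[eq] = float(r)
    norm = float(np.linalg.norm(res))
    return RecoveryResult(
        params=dict(zip(("a2", "a3", "a4", "a6", "a7", "a8"),
                        (float(v) for v in q))),
        residual_norm=norm,
        max_residual=float(np.max(np.abs(res))),
        per_fixture=per_fixture,
        success=norm < RECOVERY_FAIL_NORM,
        n_starts=n_starts,
    )


def set2_params(a1: float, a5: float) -> NondimParams:
    """The pinned recovered set-2 vector with the given (a1, a5)."""
    return NondimParams(a1=a1, a5=a5, **SET2_RECOVERED)


def pattern_scenario_params() -> NondimParams:
    """Parameters of the Turing-pattern scenario: the pinned set-2
    (a2, a4, a6, a8) with a3 = 0.1, a7 = 16 and the (a1, a5) recovered
    from the printed Turing-analysis fixture."""
    return NondimParams(
        a1=PATTERN_SCENARIO_RECOVERED["a1"],
        a5=PATTERN_SCENARIO_RECOVERED["a5"],
        a2=SET2_RECOVERED["a2"], a4=SET2_RECOVERED["a4"],
        a6=SET2_RECOVERED["a6"], a8=SET2_RECOVERED["a8"],
        a3=0.1, a7=16.0,
    )


def recover_pattern_scenario(a2: float | None = None, a4: float | None = None):
    """Recover the (a1, a5) of the Turing-analysis fixture.

    With (a2, a4) fixed (defaults: the pinned set-2 values) and
    a3 = 0.1, the fixture's f = 0 and printed (fu, fv) determine
    (a1, a5) by least squares.
    """
    fx = next(f for f in fixture_table() if f.name == "Turing")
    a2 = SET2_RECOVERED["a2"] if a2 is None else a2
    a4 = SET2_RECOVERED["a4"] if a4 is None else a4
    a6, a8 = SET2_RECOVERED["a6"], SET2_RECOVERED["a8"]

    def fun(x):
        a1, a5 = np.exp(x)
        p = NondimParams(a1=a1, a2=a2, a3=0.1, a4=a4, a5=a5,
                         a6=a6, a7=16.0, a8=a8)
        J = jacobian(fx.u, fx.v, p)
        return [reaction_f(fx.u, fx.v, p),
                J.fu - fx.jac.fu, J.fv - fx.jac.fv]

    fit = least_squares(fun, np.log([2.0, 1.0]), method="lm")
    a1, a5 = np.exp(fit.x)
    return {"a1": float(a1), "a5": float(a5),
            "residual_norm": float(np.linalg.norm(fit.fun))}


@dataclass(frozen=True)
class Scenario:
    """A named, fully specified, seeded PDE experiment."""

    name: str
    region: str
    config: PDEConfig
    expected_outcome: str

    def to_dict(self) -> dict:
        c = self.config
        return {
            "name": self.name,
            "region": self.region,
            "expected_outcome": self.expected_outcome,
            "params": {f"a{i}": getattr(c.p, f"a{i}") for i in range(1, 9)},
            "spatial": {"d": c.cfg.d, "gamma": c.cfg.gamma, "L": c.cfg.L},
            "ic": {
                "kind": c.ic.kind,
                "base": [[b.u, b.v] for b in c.ic.base],
                "eps": c.ic.eps,
                "modes": list(c.ic.modes),
                "split": c.ic.split,
            },
            "Nx": c.Nx, "t_end": c.t_end, "n_save": c.n_save,
            "rtol": c.rtol, "atol": c.atol, "seed": c.seed,
        }


def _steady_state_near(p: NondimParams, guess: tuple[float, float]) -> StatePoint:
    states = find_steady_states(p)
    if not states:
        raise RuntimeError("no steady state found")
    return min(states, key=lambda s: (s.u - guess[0]) ** 2 + (s.v - guess[1]) ** 2)


#: Paper settings per region: (a1, a5, d, gamma, L, t_end, Nx)
_REGION_SETTINGS = {
    "I": dict(a1=0.2, a5=2.0, d=10.0, gamma=500.0, L=1.0, t_end=10.0, Nx=200),
    "II": dict(d=10.0, gamma=500.0, L=1.0, t_end=10.0, Nx=200),
    # horizon long enough for the 1e-3 mode-1 perturbation to reach the
    # cycle (linear growth rate ~0.06 at gamma=100); save cadence fine
    # enough to resolve the ~0.3-time-unit oscillation period
    "III": dict(a1=4.0, a5=1.5, d=50.0, gamma=100.0, L=1.0, t_end=200.0,
                Nx=200, n_save=8001),
    "IV": dict(a1=4.3, a5=2.1, d=50.0, gamma=200.0, L=10.0, t_end=8.0,
               Nx=1000, split=9.0),
    # horizon inside the front-propagation window: the invaded state in
    # region V is unstable, and its bulk instability escapes collectively
    # at t ~ 3.2, after which the whole domain sits at the stable state
    "V": dict(a1=5.0, a5=1.5, d=50.0, gamma=200.0, L=10.0, t_end=3.0,
              Nx=1000, split=9.0),
}

_EXPECTED = {
    "I": "uniform_steady",
    "II": "turing_pattern",
    "III": "temporal_oscillation",
    "IV": "travelling_front",
    "V": "travelling_front",
}


def make_scenario(region: str, seed: int = 0,
                  gamma: float | None = None,
                  t_end: float | None = None) -> Scenario:
    """Build the canonical seeded scenario for a dynamical region.

    Regions I-III use a mode-1 perturbation (eps = 1e-3) of the uniform
    steady state.  Regions IV and V use the piecewise front seed joining
    the two coexisting attractor states, split at x = 9 on a domain of
    length 10.  Region III runs at gamma = 100 (within the range where
    the limit cycle survives diffusion) over a horizon long enough for
    the mode-1 perturbation to reach the cycle.
    """
    if region not in _REGION_SETTINGS:
        raise ValueError(f"unknown region {region!r}; "
                         f"expected one of {sorted(_REGION_SETTINGS)}")
    s = dict(_REGION_SETTINGS[region])
    if gamma is not None:
        s["gamma"] = gamma
    if t_end is not None:
        s["t_end"] = t_end

    if region == "II":
        p = pattern_scenario_params()
    else:
        p = set2_params(a1=s["a1"], a5=s["a5"])
    cfg = SpatialConfig(d=s["d"], gamma=s["gamma"], L=s["L"])

    if region in ("IV", "V"):
        states = find_steady_states(p)
        if len(states) != 3:
            raise RuntimeError(f"expected 3 steady states in region {region}")
        lo, _, hi = states
        ic = ICSpec(kind="piecewise-front", base=(lo, hi), eps=1e-3,
                    modes=(1,), split=s["split"])
    else:
        guess = {"I": (0.025, 0.18), "II": (2.3176, 4.4414),
                 "III": (0.35, 3.3)}[region]
        base = _steady_state_near(p, guess)
        ic = ICSpec(kind="mode-perturbed", base=(base,), eps=1e-3, modes=(1,))

    config = PDEConfig(p=p, cfg=cfg, ic=ic, seed=seed, Nx=s["Nx"],
                       t_end=s["t_end"], n_save=s.get("n_save", 201))
    return Scenario(name=f"region-{region}", region=region, config=config,
                    expected_outcome=_EXPECTED[region])
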