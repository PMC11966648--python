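# Methods

## The model

The package analyses the signalling network controlling local cell
contraction pulses: active Rho GTPase (R) recruits the exchange factor
GEF-H1 (G), which activates more Rho (positive feedback), while Rho also
activates myosin (M), which sequesters GEF (delayed negative feedback).
Each species cycles between an active and an inactive form with a
conserved total (RT, GT, MT), so the six-species mass-action /
Michaelis–Menten model closes to three ODEs for the active fractions.
GEF activation and inhibition are fast compared with myosin activation
(experimentally, myosin lags Rho/GEF by tens of seconds), so GEF is
eliminated by a quasi-steady-state approximation,

    Ga* = GT·k3·Ra / (k3·Ra + k4·Ma),

leaving two variables.  Nondimensionalizing with

    u = Ra·k5/k6,  v = Ma·k2·k5/k6²,  τ = t·k2·k5/k6

gives the activator–inhibitor kinetics

    f(u,v) = a1·u(a2−u) / [(a3+a2−u)(a4·v+u)] − u/(a5+u)
    g(u,v) = u(a6−v)/(a7+a6−v) − v/(a8+v)

with a1 = k1·GT/k2 proportional to total GEF (the natural bifurcation
parameter), a2 and a6 the dimensionless Rho and myosin totals (upper
bounds of the trapping box [0,a2]×[0,a6]), and a3, a5, a7, a8 rescaled
Michaelis constants.  These scalings are enforced in the test suite only
through their defining property: substituting QSSA + scalings into the
reduced three-ODE model reproduces (f, g) to machine precision, and a
nondimensional trajectory rescaled back matches a stiff dimensional
integration to 1e-3.

The analytic Jacobian uses the symbolically verified derivatives.  One
widely circulated closed form of ∂f/∂u differs from the true derivative
by a1·a3·u(1−u)/D² (a dropped exponent: the term a3(a4v(2u−a2)+u) should
read a3(a4v(2u−a2)+u²)); the package uses the true derivative, which is
cross-checked against central finite differences (rel. error < 1e-6) and
is the version consistent with the published steady-state tables (see
"Parameter recovery").

The spatial model is the two-species reaction–diffusion system

    u_t = γ f(u,v) + u_xx,   v_t = γ g(u,v) + d v_xx,   x ∈ [0, L],

with zero-flux boundaries.  d is the inhibitor/activator diffusion
ratio; γ scales kinetics relative to diffusion (γ ∝ L² under domain
rescaling).

## Parameter recovery (the synthetic stand-in for the unavailable table)

The published analysis tabulates, per dynamical region, every uniform
steady state with its (a1, a5), Jacobian and eigenvalues, but not the
underlying parameter table.  Each tabulated state pins six equations
(f = g = 0 plus four Jacobian entries) in the six shared unknowns
(a2, a3, a4, a6, a7, a8), so nine states overdetermine them ~9×.
`scenarios.recover_parameters` minimizes the stacked residuals by
Levenberg–Marquardt in log-parameter space with ≥20 log-uniform
multistarts; the minimum is unique over 300 starts, with residual norm
3.3e-4 and max per-equation residual 1.8e-4 (the printout's rounding
level).  The recovered vector is nearly exact round numbers
(a2 = 4.5000, a3 = 0.1000, a4 = 2.1053, a6 = 7.5000, a7 = 0.6075,
a8 = 7.5001), and is version-pinned and regenerated by a test.

Two tabulated entries are internally inconsistent — one eigenvalue real
part disagrees with the half-trace of its own Jacobian, and one Jacobian
corner has the wrong sign for its printed eigenvalues.  They carry
per-entry trust flags, are excluded from the fit, and are never silently
corrected in the stored fixtures.

The Turing-analysis point (a3 = 0.1, a7 = 16 substituted) gets its own
(a1, a5) the same way from its printed steady state and Jacobian with
the recovered (a2, a4) held fixed; the result (a1 = 3.0000, a5 = 1.7501,
residual 2.5e-6) reproduces the printed steady state (2.3176, 4.4414)
and all four Jacobian entries to 2e-4.

A self-consistency oracle generates fixtures from a known random vector
and requires recovery to 1e-4 relative error; a leave-one-out check
bounds the fit's sensitivity at <10% per parameter.

## Temporal analysis

Steady states: the v-nullcline is a quadratic in v after clearing
denominators, so each equilibrium is an intersection of a nullcline
branch with a sign change of f along it.  Seeds come from a 400-point
u-grid (grid-doubling changes nothing to 1e-8), are bracketed by Brent
and polished by damped Newton to residual 1e-12, deduplicated at 1e-6.
The boundary point (0,0), where f is discontinuous (limit 0 along u=0,
positive along v=0), is excluded; f(0,0)=0 is defined by continuity
along the invariant line u=0 only to regularize initial data.

Classification uses closed-form 2×2 eigenvalues (descending real part):
saddle iff det < 0, spiral iff the discriminant is negative, marginal at
|Re λ| < 1e-9.  A stable state with sign pattern (+,−;+,−) — activator
self-amplifying, inhibitor self-limiting — is a Turing (DDI) candidate.
The (a1, a5) plane decomposes into regions I (stable, non-Turing
pattern), II (stable, Turing candidate), III (unique unstable state;
stable limit cycle by Poincaré–Bendixson in the trapping box), IV
(bistable: two stable states and a saddle) and V (stable state + saddle
+ unstable spiral surrounded by a stable cycle).  With the recovered
vector the five published (a1, a5) points reproduce labels I–V, and the
regime boundaries along a5 = 1.5 fall at a1 = 1.0310, 3.9652, 4.1736,
6.2931, 6.6001 — matching the published 1.03106, 3.965, 4.174, 6.293,
6.6 and identifying a5 = 1.5 as the published baseline.

Bifurcation detection is sweep + bisection rather than pseudo-arclength:
branches are single-valued in a1 away from folds, folds appear as
equilibrium-count changes and Hopf points as sign changes of the leading
real part with nonzero imaginary part; brackets are refined to 1e-6.

Limit cycles are measured by stiff integration (LSODA, rtol 1e-8),
discarding the first half of the horizon and averaging
quadratic-interpolated successive peak intervals of u(t); "converged"
requires ≥4 peaks with interval spread < 0.1%.  Because γ only rescales
time, the default horizon is 900/γ (period·γ is exactly γ-invariant and
this is tested to 1e-4).  Near the Hopf boundary the cycle is weakly
attracting (Floquet exponent ~1e-3), so asymptotic metrics use horizons
of ~1.6e4 time units: at γ=1 the region-III cycle converges to period
30.748, amplitude 0.266.

## Turing analysis

Linearization in Neumann cosine modes gives the dispersion relation
λ² − [γT − k²(1+d)]λ + [d·k⁴ − γ(d·fu+gv)k² + γ²D] = 0 with T, D the
kinetic trace/determinant.  The four DDI conditions are T<0, D>0,
d·fu+gv>0, (d·fu+gv)² ≥ 4dD; the critical ratio d_c solves
fu²d² + (4·fv·gu − 2·fu·gv)d + gv² = 0 (the marginal double root; a
brute-force max over a 2e5-point k² grid confirms the dispersion maximum
is 0 at d_c to 1e-8).  For the Turing-point Jacobian the roots are
0.6430 and 5.8428 (published: 0.642, 5.84); instability requires
d > 5.84, i.e. the inhibitor diffusing faster.  The unstable band in k²
scales exactly linearly in γ, so mode content is controlled by γ: on
L=1 with d=10 the admissible modes are {1} at γ=500, {1,2} at γ=1000,
{2,3,4,5} at γ=5000.  Turing-space scans re-solve the steady states per
grid point and flag stable DDI candidates passing all four conditions;
the flagged region grows monotonically with d and is empty at d=1
(where the third condition equals the trace).

## PDE simulation

Method of lines: node-centred uniform grid including both endpoints,
second-order central Laplacian with mirrored ghost nodes (conservative
stencil, tested on constants and x²), fields interleaved per node so
the Jacobian is pentadiagonal, advanced by LSODA with banded structure
(rtol 1e-8, atol 1e-10).  Defaults: Nx=200 on L=1, Nx=1000 on L=10,
201 saved frames; doubling Nx changes the region-II final profile by
<1% in relative L2.  Solutions are checked against the invariant region
[0,a2]×[0,a6] (tolerance 1e-6) and for NaN.

Initial conditions follow the published recipes: u0 = u* +
ε·r(x)·Σ_n cos(nπx/L) with ε=1e-3 and r(x) per-node Uniform[0,1) draws
under a mandatory seed ("rand" is read as per-node noise — a scalar
would make the perturbation a pure eigenfunction and defeat its
purpose); piecewise-front seeds join two states at a split point, each
side perturbed identically.  Negative values (possible only for large
ε) are clipped to zero with a warning.

The L2 time-derivative diagnostic is √(Σ_x ((w(x,t+Δ)−w(x,t))/Δ)²·h)
per save interval; its decay distinguishes stationary outcomes from
sustained dynamics.

## Outcome metrics

Rules on the final third of a run: temporal diagnostic below 1e-6 and
spatial sd below 1e-4×(field scale) → uniform; temporal below, spatial
above → stationary pattern, with the dominant Neumann mode from cosine
projections of the final profile; temporal above with a periodic
midpoint signal (≥4 peaks, interval spread <5%) → oscillation, measured
at x = L/2 with the same peak estimator as the ODE path; otherwise a
travelling front is sought as a level-set trajectory X(t) (level:
midpoint of the two seeded states) that is monotone and linear with
R² > 0.99.  X(t) is tracked by continuity — each frame takes the
crossing nearest the previous position, seeded at the IC split — because
the leftmost crossing jumps to spurious intersections when the invaded
side of a region-V front oscillates through the level.  Front speed is
the least-squares slope over the middle half of the run and is
grid-convergent (<5% between Nx and 2Nx); a constructed translating
tanh profile with speed 0.3 is recovered to ±0.003.

## Canonical scenarios

Per published settings: I (a1=0.2, a5=2, d=10, γ=500, L=1, mode-1
perturbation) relaxes to the uniform state with monotonically decaying
diagnostic; II (Turing point, d=10, γ=500) forms a stationary mode-1
pattern, reproducibly across seeds; III (a1=4, a5=1.5, d=50) runs at
γ=100 — within the range where the cycle survives diffusion — for 200
time units with 8001 frames (the 1e-3 perturbation needs ~150 units to
reach the cycle at growth rate γ·Re λ ≈ 0.06, and the ~0.31-unit period
needs the fine cadence); its PDE period matches the ODE period at the
same γ within 1%.  IV and V (L=10, d=50, γ=200) use the piecewise seed
with the high-activity state on x>9.  In IV the high state invades the
low stable state as a clean travelling front (|speed| ≈ 1.3, R²>0.999).
In V the invaded state is unstable, so the front is a genuine transient:
its bulk instability (growth rate ≈1.9) escapes collectively at t≈3.2,
after which the whole domain sits at the stable state; the scenario
horizon (t_end=3) sits inside the front window.  Because the high state
invades, the interface moves from the x=9 split toward x=0; the mirror
image under x→L−x (an exact symmetry with Neumann boundaries) is the
left-to-right presentation.

## What the synthetic scenarios do and do not show

The generator reproduces the published study conditions: recovered
parameters, seeded eigenfunction-shaped noise at ε=1e-3, and the
printed (d, γ, L) per region.  It does not emulate measurement noise,
cell-geometry effects, 2-D/curved membranes, stochastic reaction events
or parameter heterogeneity — passing tests show the deterministic 1-D
model behaves as published, not that the model fits any new data.

## Known limitations

- No pseudo-arclength continuation or Floquet analysis; cycle
  boundaries come from simulation and eigenvalue sweeps.
- Fronts are tracked empirically; no linear-spreading-speed theory.
- The γ-destabilization threshold of the region-III cycle (a long PDE
  sweep in γ) is not computed by the test suite; only cycle survival at
  γ≤100 is verified.
- The dimensional Table-1 ranges gate only warnings; no fit to
  dimensional data is attempted.
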