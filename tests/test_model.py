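"""Kinetics, conservation, QSSA and nondimensionalization."""

import logging

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from rhopattern import (
    DimParams, DimState, NondimParams, dimensional_rhs6, jacobian, nondim_map,
    qssa_ga, reaction_f, reaction_g, reduced_rhs3,
)

P_SIMPLE = NondimParams(a1=2, a2=2, a3=1, a4=1, a5=1, a6=2, a7=2, a8=1)


def dim_params(**overrides) -> DimParams:
    base = dict(k1=1.0, k2=0.5, k3=1.0, k4=2.0, k5=0.3, k6=0.05,
                Km1=0.5, Km2=0.2, Km3=0.1, Km4=0.5, RT=0.8, GT=1.5, MT=1.1)
    base.update(overrides)
    return DimParams(**base)


class TestReactionKinetics:
    def test_f_vanishes_on_u_axis(self):
        assert reaction_f(0.0, 0.7, P_SIMPLE) == 0.0
        assert reaction_f(0.0, 0.0, P_SIMPLE) == 0.0  # regularized corner

    def test_f_hand_value(self):
        # 2*1*1/((2)(2)) - 1/2 = 0
        assert reaction_f(1.0, 1.0, P_SIMPLE) == pytest.approx(0.0, abs=1e-15)

    def test_f_negative_at_upper_bound(self):
        val = reaction_f(P_SIMPLE.a2, 0.5, P_SIMPLE)
        assert val == pytest.approx(-P_SIMPLE.a2 / (P_SIMPLE.a5 + P_SIMPLE.a2))
        assert val < 0

    def test_g_decay_without_activator(self):
        v = 0.8
        assert reaction_g(0.0, v, P_SIMPLE) == pytest.approx(-v / (P_SIMPLE.a8 + v))

    def test_g_at_inhibitor_cap(self):
        a6, a8 = P_SIMPLE.a6, P_SIMPLE.a8
        assert reaction_g(3.0, a6, P_SIMPLE) == pytest.approx(-a6 / (a8 + a6))

    def test_g_hand_value(self):
        # 1/3 - 1/2 = -1/6
        assert reaction_g(1.0, 1.0, P_SIMPLE) == pytest.approx(-1 / 6)

    def test_g_pole_rejected(self):
        with pytest.raises(ValueError):
            reaction_g(1.0, P_SIMPLE.a6 + P_SIMPLE.a7, P_SIMPLE)

    def test_vectorized_matches_scalar(self):
        u = np.array([0.1, 0.5, 1.0])
        v = np.array([0.2, 1.0, 1.5])
        fv = reaction_f(u, v, P_SIMPLE)
        assert fv.shape == (3,)
        for i in range(3):
            assert fv[i] == pytest.approx(reaction_f(u[i], v[i], P_SIMPLE))


class TestJacobian:
    def test_gu_vanishes_at_inhibitor_cap(self):
        J = jacobian(0.7, P_SIMPLE.a6, P_SIMPLE)
        assert J.gu == 0.0

    @given(st.integers(0, 200))
    def test_matches_finite_differences(self, k):
        rng = np.random.default_rng(k)
        a = NondimParams(*np.exp(rng.uniform(np.log(0.3), np.log(8), 8)))
        u = rng.uniform(0.05, 0.9) * a.a2
        v = rng.uniform(0.05, 0.9) * a.a6
        J = jacobian(u, v, a)
        h = 1e-6
        fd = {
            "fu": (reaction_f(u + h, v, a) - reaction_f(u - h, v, a)) / (2 * h),
            "fv": (reaction_f(u, v + h, a) - reaction_f(u, v - h, a)) / (2 * h),
            "gu": (reaction_g(u + h, v, a) - reaction_g(u - h, v, a)) / (2 * h),
            "gv": (reaction_g(u, v + h, a) - reaction_g(u, v - h, a)) / (2 * h),
        }
        scale = max(abs(x) for x in fd.values())
        for key, approx in fd.items():
            assert getattr(J, key) == pytest.approx(approx, abs=1e-6 * max(scale, 1))

    def test_trace_det_consistency(self):
        J = jacobian(0.5, 0.7, P_SIMPLE)
        assert J.trace == J.fu + J.gv
        assert J.det == J.fu * J.gv - J.fv * J.gu


class TestDimensionalModel:
    def test_conservation_exact(self, rng):
        p = dim_params()
        for _ in range(50):
            s = DimState(*rng.uniform(0.01, 1.0, 6))
            rates = dimensional_rhs6(s, p)
            assert rates[0] + rates[1] == 0.0
            assert rates[2] + rates[3] == 0.0
            assert rates[4] + rates[5] == 0.0

    def test_no_rho_activation_without_gef_or_rho(self):
        p = dim_params()
        s = DimState(Ra=0.0, Ri=0.5, Ga=0.0, Gi=0.5, Ma=0.3, Mi=0.2)
        assert dimensional_rhs6(s, p)[0] == 0.0

    def test_gef_activation_without_myosin(self):
        p = dim_params()
        s = DimState(Ra=0.4, Ri=0.1, Ga=0.2, Gi=0.8, Ma=0.0, Mi=1.0)
        assert dimensional_rhs6(s, p)[2] == pytest.approx(p.k3 * 0.4 * 0.8)
        assert dimensional_rhs6(s, p)[2] > 0

    def test_reduced_equals_full_under_conservation(self, rng):
        p = dim_params()
        for _ in range(100):
            Ra = rng.uniform(0, p.RT)
            Ga = rng.uniform(0, p.GT)
            Ma = rng.uniform(0, p.MT)
            full = dimensional_rhs6(
                DimState(Ra, p.RT - Ra, Ga, p.GT - Ga, Ma, p.MT - Ma), p)
            red = reduced_rhs3(Ra, Ga, Ma, p)
            np.testing.assert_array_equal(red, full[[0, 2, 4]])

    def test_reduced_boundary_signs(self):
        p = dim_params()
        assert reduced_rhs3(p.RT, 0.5 * p.GT, 0.5 * p.MT, p)[0] < 0
        assert reduced_rhs3(0.5 * p.RT, 0.5 * p.GT, p.MT, p)[2] < 0

    def test_out_of_range_rejected(self):
        p = dim_params()
        with pytest.raises(ValueError):
            reduced_rhs3(p.RT * 1.01, 0.1, 0.1, p)

    def test_table_range_warning_logged(self, caplog):
        with caplog.at_level(logging.WARNING):
            dim_params(k6=5.0)  # far above the calibrated range
        assert any("k6" in r.message for r in caplog.records)


class TestQSSA:
    def test_qssa_zeroes_gef_equation(self, rng):
        p = dim_params()
        for _ in range(20):
            Ra = rng.uniform(0.01, p.RT)
            Ma = rng.uniform(0.01, p.MT)
            Ga = qssa_ga(Ra, Ma, p)
            assert reduced_rhs3(Ra, Ga, Ma, p)[1] == pytest.approx(0.0, abs=1e-14)

    def test_limits(self):
        p = dim_params()
        assert qssa_ga(0.0, 0.5, p) == 0.0
        assert qssa_ga(0.0, 0.0, p) == 0.0
        Ra = 0.3
        Ma = p.k3 * Ra / p.k4
        assert qssa_ga(Ra, Ma, p) == pytest.approx(p.GT / 2)

    def test_qssa_error_decreases_with_gef_speed(self):
        """Scaling (k3, k4) by 10 and 100 shrinks the gap between the
        3-ODE model and the QSSA-reduced 2-variable model.

        Measured in a relaxing regime (small GT): in oscillatory regimes
        a phase drift between the two models dominates the sup-norm and
        masks the QSSA convergence.
        """
        errs = []
        for scale in (1.0, 10.0, 100.0):
            p = dim_params(k3=1.0 * scale, k4=2.0 * scale, GT=0.3)

            def clip(x, hi):
                return min(max(x, 0.0), hi)

            def rhs3(t, y):
                return reduced_rhs3(clip(y[0], p.RT), clip(y[1], p.GT),
                                    clip(y[2], p.MT), p)

            def rhs2(t, y):
                Ra, Ma = clip(y[0], p.RT), clip(y[1], p.MT)
                r = reduced_rhs3(Ra, qssa_ga(Ra, Ma, p), Ma, p)
                return [r[0], r[2]]

            y0 = [0.3, qssa_ga(0.3, 0.4, p), 0.4]
            full = solve_ivp(rhs3, (0, 50), y0, method="LSODA",
                             rtol=1e-10, atol=1e-12, dense_output=True)
            red = solve_ivp(rhs2, (0, 50), [y0[0], y0[2]], method="LSODA",
                            rtol=1e-10, atol=1e-12, dense_output=True)
            t = np.linspace(0, 50, 400)
            errs.append(np.max(np.abs(full.sol(t)[[0, 2]] - red.sol(t))))
        assert errs[0] > errs[1] > errs[2]


class TestNondimMap:
    def test_a1_proportional_to_GT(self):
        p1, _ = nondim_map(dim_params())
        p2, _ = nondim_map(dim_params(GT=3.0))
        assert p2.a1 == pytest.approx(p1.a1 * 2.0)
        for name in ("a2", "a3", "a4", "a5", "a6", "a7", "a8"):
            assert getattr(p2, name) == getattr(p1, name)

    def test_scaled_reduced_rhs_is_f_g(self, rng):
        """Defining property: the QSSA-reduced dimensional rates, rescaled,
        equal (f, g) exactly."""
        p = dim_params()
        nd, sc = nondim_map(p)
        for _ in range(50):
            u = rng.uniform(0.02, 0.95) * nd.a2
            v = rng.uniform(0.02, 0.95) * nd.a6
            Ra, Ma = u * sc.u_scale, v * sc.v_scale
            r = reduced_rhs3(Ra, qssa_ga(Ra, Ma, p), Ma, p)
            assert r[0] * sc.t_scale / sc.u_scale == pytest.approx(
                reaction_f(u, v, nd), rel=1e-12, abs=1e-12)
            assert r[2] * sc.t_scale / sc.v_scale == pytest.approx(
                reaction_g(u, v, nd), rel=1e-12, abs=1e-12)

    def test_roundtrip_trajectory(self):
        """A nondimensional trajectory rescaled to dimensional variables
        matches a direct stiff integration of the reduced model + QSSA."""
        p = dim_params()
        nd, sc = nondim_map(p)
        u0, v0 = 0.3 * nd.a2, 0.3 * nd.a6
        t_end_nd = 5.0

        ndsol = solve_ivp(
            lambda t, y: [reaction_f(y[0], y[1], nd), reaction_g(y[0], y[1], nd)],
            (0, t_end_nd), [u0, v0], method="LSODA", rtol=1e-10, atol=1e-12,
            dense_output=True)

        def rhs2(t, y):
            r = reduced_rhs3(y[0], qssa_ga(y[0], y[1], p), y[1], p)
            return [r[0], r[2]]

        dsol = solve_ivp(rhs2, (0, t_end_nd * sc.t_scale),
                         [u0 * sc.u_scale, v0 * sc.v_scale],
                         method="LSODA", rtol=1e-10, atol=1e-12,
                         dense_output=True)
        t_nd = np.linspace(0, t_end_nd, 200)
        nd_traj = ndsol.sol(t_nd)
        d_traj = dsol.sol(t_nd * sc.t_scale)
        assert np.max(np.abs(nd_traj[0] * sc.u_scale - d_traj[0])) < 1e-3 * max(
            d_traj[0].max(), 1e-12)
        assert np.max(np.abs(nd_traj[1] * sc.v_scale - d_traj[1])) < 1e-3 * max(
            d_traj[1].max(), 1e-12)


class TestTrappingBox:
    """Trajectories started in [0, a2] x [0, a6] remain there."""

    @pytest.mark.parametrize("a1,a5", [(0.2, 2.0), (2.0, 1.0), (4.3, 2.1)])
    def test_boundary_signs(self, a1, a5):
        from rhopattern import set2_params
        p = set2_params(a1=a1, a5=a5)
        for v in np.linspace(0, p.a6, 7):
            assert reaction_f(p.a2, v, p) < 0
            assert reaction_f(0.0, v, p) == 0.0
        for u in np.linspace(0.01, p.a2, 7):
            assert reaction_g(u, p.a6, p) < 0
            assert reaction_g(u, 0.0, p) >= 0

    @pytest.mark.parametrize("a1,a5", [(0.2, 2.0), (4.0, 1.5), (4.3, 2.1)])
    def test_trajectories_stay_inside(self, a1, a5, rng):
        from rhopattern import set2_params
        p = set2_params(a1=a1, a5=a5)
        tol = 1e-9
        starts = rng.uniform([0.01, 0.01], [0.99, 0.99], size=(30, 2))
        for su, sv in starts:
            sol = solve_ivp(
                lambda t, y: [reaction_f(y[0], y[1], p),
                              reaction_g(y[0], y[1], p)],
                (0, 50), [su * p.a2, sv * p.a6], method="LSODA",
                rtol=1e-8, atol=1e-10)
            assert sol.success
            assert np.all(sol.y[0] >= -tol) and np.all(sol.y[0] <= p.a2 + tol)
            assert np.all(sol.y[1] >= -tol) and np.all(sol.y[1] <= p.a6 + tol)
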