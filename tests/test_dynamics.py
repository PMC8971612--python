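"""Rigid-body dynamics oracles: pendulum closed form, Lagrangian cross-check,
energy conservation, inverse-dynamics round trips, seat constraint contracts
and balance bookkeeping."""

import numpy as np
import pytest

import planarsts as ps
from planarsts import _kernels as K
from planarsts.dynamics import (bias_forces, forward_dynamics, hip_point,
                                inverse_dynamics, mass_matrix,
                                mechanical_energy)
from planarsts.muscles import joint_torques
from planarsts.params import DEG
from planarsts.simulate import initial_state, simulate


@pytest.fixture(scope="module")
def lagrangian_oracle(default_model):
    """Sympy-derived mass matrix and bias for the 3-link chain.

    Independent of the closed-form implementation: builds the Lagrangian
    from the segment geometry and differentiates symbolically.
    """
    import sympy as sp

    segs = default_model.segments
    L1, L2 = segs[0].length, segs[1].length
    offs = [s.com_offset for s in segs]
    fwd = [getattr(s, "com_forward", 0.0) for s in segs]
    ms = [s.mass for s in segs]
    Is = [s.inertia for s in segs]
    g = default_model.gravity
    ax, ay = default_model.foot.ankle

    t = sp.symbols("t")
    qf = [sp.Function(f"q{i}")(t) for i in range(3)]
    phi = [qf[0], qf[0] - qf[1], qf[0] - qf[1] + qf[2]]
    acoef = [[offs[0], 0, 0], [L1, offs[1], 0], [L1, L2, offs[2]]]

    T = 0
    V = 0
    for i in range(3):
        x = ax + sum(acoef[i][j] * sp.sin(phi[j]) for j in range(3)) \
            + fwd[i] * sp.cos(phi[i])
        y = ay + sum(acoef[i][j] * sp.cos(phi[j]) for j in range(3)) \
            - fwd[i] * sp.sin(phi[i])
        vx = sp.diff(x, t)
        vy = sp.diff(y, t)
        T += sp.Rational(1, 2) * ms[i] * (vx**2 + vy**2) \
            + sp.Rational(1, 2) * Is[i] * sp.diff(phi[i], t) ** 2
        V += ms[i] * g * y
    Lag = T - V

    qs = sp.symbols("a b c")
    qds = sp.symbols("da db dc")
    qdds = sp.symbols("dda ddb ddc")
    eoms = []
    for j in range(3):
        eq = sp.diff(sp.diff(Lag, sp.diff(qf[j], t)), t) - sp.diff(Lag, qf[j])
        for k in range(3):
            eq = eq.subs(sp.diff(qf[k], t, 2), qdds[k])
        for k in range(3):
            eq = eq.subs(sp.diff(qf[k], t), qds[k])
        for k in range(3):
            eq = eq.subs(qf[k], qs[k])
        eoms.append(sp.expand(eq))

    func = sp.lambdify((*qs, *qds, *qdds), eoms, "numpy")

    def generalized_forces(q, qd, qdd):
        return np.asarray(func(*q, *qd, *qdd), dtype=float)

    return generalized_forces


def test_mass_matrix_and_bias_match_symbolic_lagrangian(default_model,
                                                        lagrangian_oracle):
    rng = np.random.default_rng(42)
    for _ in range(10):
        q = rng.uniform(-1.2, 1.8, 3)
        qd = rng.uniform(-3, 3, 3)
        qdd = rng.uniform(-10, 10, 3)
        expected = lagrangian_oracle(q, qd, qdd)
        got = mass_matrix(default_model, q) @ qdd + bias_forces(default_model, q, qd)
        np.testing.assert_allclose(got, expected, rtol=1e-9, atol=1e-9)


def test_upright_rest_zero_gravity_is_equilibrium(default_model):
    cfg = ps.default_model_config()
    cfg["gravity"] = 0.0
    m0 = ps.build_model(cfg)
    qdd, _ = forward_dynamics(m0, np.zeros(3), np.zeros(3), np.zeros(3))
    np.testing.assert_allclose(qdd, 0.0, atol=1e-12)


def test_locked_knee_hip_matches_compound_pendulum(default_model):
    """Whole chain rotating about the ankle = compound pendulum closed form."""
    segs = default_model.segments
    L1, L2 = segs[0].length, segs[1].length
    ax_d = [segs[0].com_offset, L1 + segs[1].com_offset,
            L1 + L2 + segs[2].com_offset]
    fwd = [getattr(s, "com_forward", 0.0) for s in segs]
    d = [np.hypot(a, f) for a, f in zip(ax_d, fwd)]
    delta = [np.arctan2(f, a) for a, f in zip(ax_d, fwd)]
    m = [s.mass for s in segs]
    I_tot = sum(s.inertia + mi * di**2 for s, mi, di in zip(segs, m, d))
    g = default_model.gravity

    for theta in (0.05, -0.12, 0.3):
        q = np.array([theta, 0.0, 0.0])
        qdd, _ = forward_dynamics(default_model, q, np.zeros(3), np.zeros(3),
                                  locked_joints=("knee", "hip"))
        # falls away from the (COM-offset-shifted) balance angle
        expected = g * sum(mi * di * np.sin(theta + de)
                           for mi, di, de in zip(m, d, delta)) / I_tot
        assert qdd[0] == pytest.approx(expected, rel=1e-6)
        assert qdd[1] == 0.0 and qdd[2] == 0.0


def test_forward_inverse_round_trip_unconstrained(default_model):
    rng = np.random.default_rng(7)
    for _ in range(100):
        q = rng.uniform(-1.0, 1.8, 3)
        qd = rng.uniform(-4, 4, 3)
        tau = rng.uniform(-80, 80, 3)
        fa = rng.uniform(-100, 100, 2)
        qdd, _ = forward_dynamics(default_model, q, qd, tau, assist_force=fa)
        tau_back = inverse_dynamics(default_model, q, qd, qdd, assist_force=fa)
        np.testing.assert_allclose(tau_back, tau, rtol=1e-6, atol=1e-8)


def test_forward_inverse_round_trip_with_seat(default_model):
    """On-manifold constrained states: ID with the multiplier force closes."""
    rng = np.random.default_rng(8)
    q_sit = default_model.sitting_q()
    for _ in range(50):
        q = np.array([q_sit[0], q_sit[1], rng.uniform(0.3, 1.9)])
        qd = np.array([0.0, 0.0, rng.uniform(-3, 3)])
        tau = rng.uniform(-60, 60, 3)
        qdd, lam = forward_dynamics(default_model, q, qd, tau, seat_engaged=True)
        tau_back = inverse_dynamics(default_model, q, qd, qdd, seat_force=lam)
        np.testing.assert_allclose(tau_back, tau, rtol=1e-6, atol=1e-7)


def test_passive_energy_conservation(default_model, layout):
    """Unconstrained passive fall keeps total mechanical energy constant.

    Released near upright with a small lean the chain falls and swings
    through 1.6 s without exceeding physiological speeds.
    """
    from planarsts.params import IntegratorConfig

    st = initial_state(default_model)
    st.seat_engaged = False
    st.q = np.array([0.10, 0.20, -0.10])
    st.qdot = np.zeros(3)
    traj = ps.decode(ps.sitting_guess(layout), layout)
    # the free fall whips the light shank to ~50 rad/s, an order of
    # magnitude beyond any sit-to-stand; halve the step (and lift the
    # divergence cap) for commensurate accuracy on this stress case
    integ = IntegratorConfig(dt=0.0005, qdot_cap=1e9)
    res = simulate(default_model, traj, start=st, integrator=integ,
                   use_muscles=False, use_springs=False)
    assert not res.failed
    e = np.array([mechanical_energy(default_model, res.q[i], res.qdot[i])
                  for i in range(0, res.n_samples, 20)])
    drift = np.max(np.abs(e - e[0]))
    assert drift < 1e-4 * abs(e[0])


def test_static_sitting_force_balance(default_model):
    """Seated static equilibrium: seat F_y + feet F_y carries the body weight."""
    pm = ps.pack_model(default_model)
    q = default_model.sitting_q()
    qd = np.zeros(3)

    # hip torque that makes the seated torso static (qdd linear in tau_hip)
    def qdd_hip(tau_h):
        qdd, _ = forward_dynamics(default_model, q, qd, np.array([0, 0, tau_h]),
                                  seat_engaged=True)
        return qdd[2]

    a0 = qdd_hip(0.0)
    a1 = qdd_hip(1.0)
    tau_h = -a0 / (a1 - a0)
    qdd, lam = forward_dynamics(default_model, q, qd,
                                np.array([0.0, 0.0, tau_h]), seat_engaged=True)
    assert np.max(np.abs(qdd)) < 1e-8
    _, _, feet, _ = K.instrument(q, qd, qdd, lam, 0.0, 0.0,
                                 pm.masses, pm.Iseg, pm.acoef, pm.dphase, pm.g,
                                 pm.L1, pm.L2, pm.ax, pm.ay,
                                 pm.m_foot, pm.fcx, pm.fcy)
    total = feet[1] + lam[1]
    assert total == pytest.approx(default_model.weight, rel=1e-6)
    assert lam[1] > 0  # chair actually carries load


def test_seat_monotonicity_and_compressive_contract(active_rollout):
    res = active_rollout
    assert res.released
    engaged = res.times < res.t_seat_release
    # compressive while engaged, identically zero after
    assert np.all(res.seat_force[engaged, 1] >= 0)
    assert np.all(res.seat_force[~engaged] == 0.0)
    # engaged flags non-increasing
    flags = engaged.astype(int)
    assert np.all(np.diff(flags) <= 0)


def test_weld_wrench_balance_newton_euler(default_model, active_rollout):
    """Impulse of feet + seat + assist + gravity equals the momentum change.

    Newton-Euler oracle in integral form: over every 0.1 s window the
    trapezoid impulse of all external forces matches the whole-body
    momentum difference computed independently from the COM velocity.
    """
    res = active_rollout
    total_m = default_model.total_mass
    mom = total_m * res.com_vel
    grav = np.array([0.0, -default_model.weight])
    force = res.feet_force + res.seat_force + res.assist_force + grav
    t = res.times
    idx = np.searchsorted(t, np.arange(t[0], t[-1], 0.1))
    for a, b in zip(idx[:-1], idx[1:]):
        if t[a] <= res.t_seat_release <= t[b]:
            continue  # trapezoid cannot integrate the release jump
        impulse = np.trapezoid(force[a:b + 1], t[a:b + 1], axis=0)
        dmom = mom[b] - mom[a]
        # tolerance: 0.25 % of body weight over the window (trapezoid error
        # concentrates at limit-spring engagement kinks)
        np.testing.assert_allclose(impulse, dmom,
                                   atol=2.5e-3 * default_model.weight * 0.1)


def test_check_seat_release_conditions():
    assert ps.check_seat_release((0.0, -10.0), mu=0.8)       # non-compressive
    assert not ps.check_seat_release((10.0, 100.0), mu=0.8)  # inside cone
    assert ps.check_seat_release((90.0, 100.0), mu=0.8)      # slipping


def test_limit_spring_torque_contract(default_model):
    knee = default_model.limit_for("knee")
    assert ps.limit_spring_torque(knee, 70 * DEG) == 0.0
    assert ps.limit_spring_torque(knee, 150 * DEG) < 0.0     # extension-restoring
    assert ps.limit_spring_torque(knee, -5 * DEG) > 0.0      # flexion-restoring
    # continuous at the limit
    assert abs(ps.limit_spring_torque(knee, 140 * DEG)) < 1e-12
    # magnitude equals the configured stiffening curve at 5 deg overshoot
    ankle = default_model.limit_for("ankle")
    got = ps.limit_spring_torque(ankle, 35 * DEG)
    expected = -ankle.scale * (np.exp(ankle.rate * 5 * DEG) - 1.0)
    assert got == pytest.approx(expected, rel=1e-12)


def test_com_is_mass_weighted_mean(default_model):
    rng = np.random.default_rng(3)
    segs = default_model.segments
    foot = default_model.foot
    for _ in range(10):
        q = rng.uniform(-0.5, 1.5, 3)
        phi = np.array([q[0], q[0] - q[1], q[0] - q[1] + q[2]])
        u = np.stack([np.sin(phi), np.cos(phi)], axis=1)
        ankle = np.asarray(foot.ankle)
        knee = ankle + segs[0].length * u[0]
        hip = knee + segs[1].length * u[1]
        e = np.stack([np.cos(phi), -np.sin(phi)], axis=1)
        coms = [ankle + segs[0].com_offset * u[0]
                + getattr(segs[0], "com_forward", 0.0) * e[0],
                knee + segs[1].com_offset * u[1]
                + getattr(segs[1], "com_forward", 0.0) * e[1],
                hip + segs[2].com_offset * u[2]
                + getattr(segs[2], "com_forward", 0.0) * e[2]]
        total = sum(s.mass for s in segs) + foot.mass
        expected = (sum(s.mass * c for s, c in zip(segs, coms))
                    + foot.mass * np.asarray(foot.com)) / total
        np.testing.assert_allclose(ps.compute_com(default_model, q), expected,
                                   atol=1e-12)
    np.testing.assert_allclose(
        ps.compute_com_vel(default_model, rng.uniform(-1, 1, 3), np.zeros(3)),
        0.0, atol=1e-15)


def test_com_upright_above_ankle(default_model):
    com = ps.compute_com(default_model, np.zeros(3))
    # stacked over the ankle, shifted slightly toe-ward by the anterior
    # HAT centre of mass and the foot mass
    assert 0.0 < com[0] - default_model.foot.ankle[0] < 0.04


def test_zmp_moment_balance():
    assert ps.compute_zmp((0.0, 750.0), 0.0, 0.05) == pytest.approx(0.05)
    assert ps.compute_zmp((0.0, 750.0), 75.0, 0.0) == pytest.approx(-0.1)
    with pytest.raises(ps.ZmpUndefinedError):
        ps.compute_zmp((0.0, -1.0), 0.0, 0.0)


def test_zmp_static_weight_line(default_model):
    """Static seated ZMP equals the independent moment-balance construction."""
    pm = ps.pack_model(default_model)
    q = default_model.sitting_q()
    qd = np.zeros(3)

    def qdd_hip(tau_h):
        qdd, _ = forward_dynamics(default_model, q, qd,
                                  np.array([0, 0, tau_h]), seat_engaged=True)
        return qdd[2]

    a0, a1 = qdd_hip(0.0), qdd_hip(1.0)
    tau_h = -a0 / (a1 - a0)
    qdd, lam = forward_dynamics(default_model, q, qd,
                                np.array([0, 0, tau_h]), seat_engaged=True)
    _, _, feet, fm = K.instrument(q, qd, qdd, lam, 0.0, 0.0,
                                  pm.masses, pm.Iseg, pm.acoef, pm.dphase, pm.g,
                                  pm.L1, pm.L2, pm.ax, pm.ay,
                                  pm.m_foot, pm.fcx, pm.fcy)
    zmp = ps.compute_zmp(feet, fm, pm.ax)

    # independent static oracle: moments of gravity and seat reaction about
    # the ZMP point must cancel the feet force moment
    p, hip, _ = K.body_points(q, pm.acoef, pm.dphase, pm.ax, pm.ay, pm.L1, pm.L2)
    g = default_model.gravity
    num = (sum(pm.masses[i] * g * p[i, 0] for i in range(3))
           + pm.m_foot * g * pm.fcx - pm.sx * lam[1] + pm.sy * lam[0])
    zmp_oracle = num / feet[1]
    assert zmp == pytest.approx(zmp_oracle, abs=1e-9)


def test_divergence_cap_flags_partial_result(default_model, layout):
    """An absurd integrator cap aborts the roll-out but keeps the series."""
    from planarsts.params import IntegratorConfig

    st = initial_state(default_model)
    st.seat_engaged = False
    st.qdot = np.array([3.0, -3.0, 3.0])
    traj = ps.decode(ps.sitting_guess(layout), layout)
    res = simulate(default_model, traj,
                   integrator=IntegratorConfig(dt=0.001, qdot_cap=3.5),
                   start=st, use_muscles=False, use_springs=False)
    assert res.failed
    assert res.n_samples < len(np.arange(0, traj.t_f + 1e-9, 0.001))
    b = ps.compute_terms(res, default_model)  # still evaluable by the cost
    assert np.isfinite(b.total)


def test_simulation_degenerate_zero_duration(default_model, layout):
    traj = ps.ControlTrajectory(layout=layout,
                                node_values=np.full((8, 16), 0.05), t_f=0.0)
    res = simulate(default_model, traj)
    assert res.n_samples == 1
    b = ps.compute_terms(res, default_model)
    np.testing.assert_allclose(b.cf, b.c0)
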